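"""Independent brute-force oracles, deliberately written as naive nested
conditionals / all-pairs loops so they share no code path with the package."""

from __future__ import annotations


def oracle_score(score_id: str, pt=None, dd=None, fib=None, plt=None,
                 ldh=None, hgb=None, inr=None, gen=None) -> int:
    """Hand-coded nested-conditional total for each scoring system.

    Values at a published threshold fall to the lower-point bin except
    where the published rule is >= / <= (LDH, INR, Hgb).
    """

    def pt_pts():
        prol = pt - 13.5
        if prol < 0:
            prol = 0.0
        if prol <= 3:
            return 0
        elif prol <= 6:
            return 1
        else:
            return 2

    def dd_pts():
        if dd < 500:
            return 0
        elif dd <= 4000:
            return 2
        else:
            return 3

    def fib_pts():
        if fib >= 100:
            return 0
        else:
            return 1

    def plt_pts():
        if plt >= 100:
            return 0
        elif plt >= 50:
            return 1
        else:
            return 2

    def ldh400_pts():
        return 1 if ldh >= 400 else 0

    def ldh800_pts():
        return 1 if ldh >= 800 else 0

    def hgb_pts():
        return 0 if hgb >= 7 else 1

    def inr_pts():
        return 0 if inr <= 1.2 else 1

    def gen_pts():
        return 1 if gen else 0

    core = None
    if score_id in ("ORIGINAL", "M1", "M2", "M3", "M4", "M5"):
        core = pt_pts() + dd_pts() + fib_pts() + plt_pts()
    if score_id == "ORIGINAL":
        return core
    elif score_id == "M1":
        return core + ldh400_pts()
    elif score_id == "M2":
        return core + ldh800_pts()
    elif score_id == "M3":
        return core + gen_pts()
    elif score_id == "M4":
        return core + hgb_pts()
    elif score_id == "M5":
        return core + inr_pts()
    elif score_id == "M6":
        return pt_pts() + fib_pts() + plt_pts() + ldh400_pts() + gen_pts()
    elif score_id == "M7":
        return pt_pts() + fib_pts() + plt_pts() + ldh800_pts() + gen_pts()
    elif score_id == "M8":
        return pt_pts() + fib_pts() + plt_pts() + gen_pts()
    raise ValueError(score_id)


ORACLE_THRESHOLDS = {
    "ORIGINAL": 5, "M1": 6, "M2": 6, "M3": 6, "M4": 6, "M5": 6,
    "M6": 5, "M7": 5, "M8": 4,
}


def oracle_auc(scores, outcomes) -> float:
    """All-pairs AUC: 1 per correctly ordered bleeder/non-bleeder pair,
    1/2 per tie."""
    pos = [s for s, o in zip(scores, outcomes) if o]
    neg = [s for s, o in zip(scores, outcomes) if not o]
    total = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                total += 1.0
            elif a == b:
                total += 0.5
    return total / (len(pos) * len(neg))
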