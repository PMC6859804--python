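"""Net diversification rates from standing richness and clade age.

Implements the standardized whole-clade estimators of Magallon & Sanderson
(2001): given n extant species, a clade age t (Myr) and a relative extinction
fraction epsilon = mu/lambda, the net rate r = lambda - mu is the value that
makes the expected richness of a surviving clade equal n.

With epsilon = 0 the estimators reduce to the closed forms

    crown:  r = (ln n - ln 2) / t        (n >= 2)
    stem:   r = ln n / t                 (n >= 1)

and for epsilon > 0 the crown form is

    r = (1/t) * [ ln( n (1 - e^2)/2 + 2 e
                    + (1 - e)/2 * sqrt( n (n e^2 + 2 n e - 8 e + n) ) )
                  - ln 2 ]

which is continuous in epsilon with the epsilon -> 0 limit equal to the
closed form.  Rates are reported in species/Myr; rounding to two decimals
happens only at report time.
"""

from __future__ import annotations

import math

import pandas as pd

#: qualitative class bins inferred from published rate labels
CLASS_BINS = [(2.0, "Very fast"), (1.0, "Fast"), (0.0, "Medium")]


def _validate(n: float, t: float, epsilon: float, n_min: int) -> None:
    if n < n_min:
        raise ValueError(f"n must be >= {n_min}, got {n}")
    if t <= 0:
        raise ValueError(f"t must be > 0, got {t}")
    if not 0.0 <= epsilon < 1.0:
        raise ValueError(f"epsilon must be in [0, 1), got {epsilon}")


def crown_divrate(n: float, t: float, epsilon: float = 0.0) -> float:
    """Whole-clade net diversification rate from crown age."""
    _validate(n, t, epsilon, n_min=2)
    if epsilon == 0.0:
        return (math.log(n) - math.log(2.0)) / t
    e = epsilon
    inner = (
        n * (1.0 - e * e) / 2.0
        + 2.0 * e
        + (1.0 - e) / 2.0 * math.sqrt(n * (n * e * e + 2.0 * n * e - 8.0 * e + n))
    )
    return (math.log(inner) - math.log(2.0)) / t


def stem_divrate(n: float, t: float, epsilon: float = 0.0) -> float:
    """Whole-clade net diversification rate from stem age."""
    _validate(n, t, epsilon, n_min=1)
    return math.log(n * (1.0 - epsilon) + epsilon) / t


def classify_rate(r: float) -> str:
    for lo, label in CLASS_BINS:
        if r >= lo:
            return label
    return "Medium"


def divrate_table(records: pd.DataFrame, epsilon: float = 0.0) -> pd.DataFrame:
    """Fill rates and qualitative classes for a clade richness/age table.

    ``records`` needs columns ``clade``, ``n``, ``age`` and optionally
    ``age_type`` (crown/stem, default crown).  Returns a copy with ``rate``
    (2 dp) and ``class`` columns appended.
    """
    out = records.copy()
    rates = []
    for _, row in out.iterrows():
        age_type = str(row.get("age_type", "crown") or "crown").lower()
        if age_type == "crown":
            r = crown_divrate(float(row["n"]), float(row["age"]), epsilon)
        elif age_type == "stem":
            r = stem_divrate(float(row["n"]), float(row["age"]), epsilon)
        else:
            raise ValueError(f"unknown age_type {age_type!r}")
        rates.append(r)
    out["rate"] = [round(r, 2) for r in rates]
    out["class"] = [classify_rate(r) for r in rates]
    return out
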