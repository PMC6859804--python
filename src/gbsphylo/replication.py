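"""Replicate-based genotyping-error statistics.

Two DNA extractions of the same individual, sequenced and assembled
independently, should yield identical genotypes; their disagreements measure
the error introduced by the pipeline.  Three levels are quantified:

* locus error  — loci recovered in exactly one replicate / loci in at least
  one replicate (union denominator: symmetric, bounded, 0 and 1 at the
  extremes);
* allele error — shared loci whose consensus sequences differ (allele-set
  comparison; columns where either copy is N/- are ignored) / shared loci;
* SNP error    — assembly-wide SNP columns inside shared loci where both
  genotypes are resolved, split into *hard* (disjoint allele sets) and
  *heterozygous* (intersecting but unequal) classes over one shared
  denominator, so snp = hard + het.

Undefined rates (empty denominators) are reported as NaN, never as 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .iupac import POPCOUNT
from .loci import Assembly, classify_columns, encode


class UndefinedRateError(ValueError):
    """A rate whose denominator is empty."""


RATE_COLUMNS = ["locus_error", "allele_error", "snp_error", "hard_error", "het_error"]


@dataclass
class ErrorRateReport:
    """Per-pair error rates plus their unweighted means.

    ``per_pair`` is indexed by sample label, with rate and count columns;
    undefined rates are NaN and excluded from the means.
    """

    per_pair: pd.DataFrame
    mean: pd.Series

    def to_csv(self, path) -> None:
        df = self.per_pair.copy()
        df.loc["mean"] = self.mean
        df.to_csv(path, float_format="%.4f")


def _locus_ids(assembly: Assembly, sample: str) -> set[str]:
    return {loc.locus_id for loc in assembly.loci if sample in loc.samples}


def _check_pair(assembly: Assembly, rep_a: str, rep_b: str) -> None:
    for rep in (rep_a, rep_b):
        if rep not in assembly.roster:
            raise ValueError(f"replicate {rep!r} not in assembly roster")


def locus_error(assembly: Assembly, rep_a: str, rep_b: str) -> tuple[float, dict]:
    """Fraction of the pair's locus union recovered in only one replicate."""
    _check_pair(assembly, rep_a, rep_b)
    a, b = _locus_ids(assembly, rep_a), _locus_ids(assembly, rep_b)
    union = a | b
    if not union:
        raise UndefinedRateError(f"pair ({rep_a}, {rep_b}): no loci in either replicate")
    discordant = len(a ^ b)
    counts = {"union_loci": len(union), "discordant_loci": discordant,
              "shared_loci": len(a & b)}
    return discordant / len(union), counts


def allele_error(assembly: Assembly, rep_a: str, rep_b: str) -> tuple[float, dict]:
    """Fraction of shared loci whose sequences differ between replicates.

    A locus differs when any column with both copies non-missing carries
    unequal allele sets (distinct IUPAC characters).
    """
    _check_pair(assembly, rep_a, rep_b)
    shared = differing = 0
    for loc in assembly.loci:
        if rep_a not in loc.samples or rep_b not in loc.samples:
            continue
        shared += 1
        ma, mb = encode(loc.samples[rep_a]), encode(loc.samples[rep_b])
        both = (ma != 0) & (mb != 0)
        if np.any(ma[both] != mb[both]):
            differing += 1
    if shared == 0:
        raise UndefinedRateError(f"pair ({rep_a}, {rep_b}): no shared loci")
    counts = {"shared_loci": shared, "differing_loci": differing}
    return differing / shared, counts


def snp_errors(
    assembly: Assembly, rep_a: str, rep_b: str
) -> tuple[float, float, float, dict]:
    """(snp, hard, het) error rates over shared, both-resolved SNP columns."""
    _check_pair(assembly, rep_a, rep_b)
    eligible = hard = het = 0
    for loc in assembly.loci:
        if rep_a not in loc.samples or rep_b not in loc.samples:
            continue
        snp_cols = classify_columns(loc)["snp"]
        if not snp_cols.any():
            continue
        ma, mb = encode(loc.samples[rep_a]), encode(loc.samples[rep_b])
        use = snp_cols & (ma != 0) & (mb != 0)
        eligible += int(use.sum())
        diff = use & (ma != mb)
        inter = POPCOUNT[ma & mb] > 0
        hard += int((diff & ~inter).sum())
        het += int((diff & inter).sum())
    if eligible == 0:
        raise UndefinedRateError(f"pair ({rep_a}, {rep_b}): no eligible SNP sites")
    counts = {"eligible_snp_sites": eligible, "hard_sites": hard, "het_sites": het}
    return (hard + het) / eligible, hard / eligible, het / eligible, counts


def error_report(assembly: Assembly, pairing: list[tuple[str, str, str]]) -> ErrorRateReport:
    """Per-pair rates plus unweighted arithmetic means across pairs.

    Pairs whose denominator for a given rate is empty contribute NaN to that
    rate and are excluded from its mean.
    """
    if not pairing:
        raise ValueError("empty pairing")
    rows = []
    for sample, rep_a, rep_b in pairing:
        row: dict[str, float] = {"sample": sample}
        try:
            row["locus_error"], c = locus_error(assembly, rep_a, rep_b)
            row.update({k: c[k] for k in ("union_loci", "discordant_loci", "shared_loci")})
        except UndefinedRateError:
            row["locus_error"] = np.nan
        try:
            row["allele_error"], c = allele_error(assembly, rep_a, rep_b)
            row["differing_loci"] = c["differing_loci"]
        except UndefinedRateError:
            row["allele_error"] = np.nan
        try:
            snp, hard, het, c = snp_errors(assembly, rep_a, rep_b)
            row.update(snp_error=snp, hard_error=hard, het_error=het, **c)
        except UndefinedRateError:
            row.update(snp_error=np.nan, hard_error=np.nan, het_error=np.nan)
        rows.append(row)
    per_pair = pd.DataFrame(rows).set_index("sample")
    mean = per_pair.mean(skipna=True)
    return ErrorRateReport(per_pair, mean)


def read_pairing_csv(path) -> list[tuple[str, str, str]]:
    """Pairing table CSV with columns sample,replicateA,replicateB."""
    df = pd.read_csv(path)
    cols = [c.lower() for c in df.columns]
    df.columns = cols
    return [
        (str(r["sample"]), str(r["replicatea"]), str(r["replicateb"]))
        for _, r in df.iterrows()
    ]
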