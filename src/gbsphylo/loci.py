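"""Multi-locus assembly containers, the ``.loci`` dialect, and summary statistics.

An assembly is the unit of a reduced-representation (GBS/RADseq) pipeline run:
a set of per-locus alignments of IUPAC-coded diploid consensus sequences, one
row per sample, plus the nominal parameter configuration that produced it.
The on-disk format is the classic pyRAD ``.loci`` dialect: blocks of
``>sample<ws><sequence>`` lines closed by a ``//`` marker row whose columns
flag variable (``-``) and parsimony-informative (``*``) sites.

Site classification works on allele sets: an ambiguity code contributes both
of its alleles to variability, while parsimony-informative / singleton calls
count *samples* carrying an allele.  ``N`` and ``-`` are missing data.
Internal coordinates are 0-based half-open; emitted reports are 1-based
inclusive.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .iupac import MASK_LUT, POPCOUNT, VALID_CHARS, encode


class LociParseError(ValueError):
    """Malformed ``.loci`` input (ragged block, unknown character, ...)."""


@dataclass
class LocusAlignment:
    """One recovered locus: aligned consensus sequences keyed by sample.

    ``samples`` preserves insertion order; all sequences must share one length.
    """

    locus_id: str
    samples: dict[str, str]

    def __post_init__(self) -> None:
        if not self.samples:
            raise ValueError(f"locus {self.locus_id}: no samples")
        lengths = {len(s) for s in self.samples.values()}
        if len(lengths) != 1:
            raise LociParseError(
                f"locus {self.locus_id}: ragged alignment, lengths {sorted(lengths)}"
            )

    @property
    def length(self) -> int:
        return len(next(iter(self.samples.values())))

    def matrix(self) -> np.ndarray:
        """(n_samples, length) allele-bitmask matrix in ``samples`` order."""
        return np.vstack([encode(s) for s in self.samples.values()])


@dataclass
class Assembly:
    """A set of loci plus the global sample roster and configuration metadata."""

    loci: list[LocusAlignment]
    roster: list[str]
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        roster = set(self.roster)
        if len(roster) != len(self.roster):
            raise ValueError("roster labels not unique")
        for loc in self.loci:
            extra = set(loc.samples) - roster
            if extra:
                raise ValueError(
                    f"locus {loc.locus_id}: samples {sorted(extra)} not in roster"
                )

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def total_bp(self) -> int:
        return sum(loc.length for loc in self.loci)

    def subset_samples(self, names: list[str]) -> "Assembly":
        """Restrict to the given samples, dropping loci left empty."""
        keep = [n for n in self.roster if n in set(names)]
        loci = []
        for loc in self.loci:
            samples = {s: q for s, q in loc.samples.items() if s in set(keep)}
            if samples:
                loci.append(LocusAlignment(loc.locus_id, samples))
        return Assembly(loci, keep, dict(self.config))


@dataclass(frozen=True)
class AssemblyStats:
    """Whole-assembly summary: size, variability and missing-data metrics."""

    n_loci: int
    total_bp: int
    n_snps: int
    n_pis: int
    n_singletons: int
    pct_missing: float


# ---------------------------------------------------------------------------
# column classification


def classify_columns(locus: LocusAlignment) -> dict[str, np.ndarray]:
    """Per-column classification of one locus.

    Returns boolean arrays ``snp`` (>1 distinct allele over all allele
    copies), ``pis`` (>=2 alleles each carried by >=2 samples), ``singleton``
    (variable column where all but one present sample share one genotype
    pattern), and the integer array ``n_missing`` (N/- cells per column).
    """
    m = locus.matrix()
    present = m != 0
    n_present = present.sum(axis=0)
    union = np.bitwise_or.reduce(m, axis=0)
    snp = POPCOUNT[union] > 1

    carriers = np.zeros((4, m.shape[1]), dtype=np.int64)
    for bit in range(4):
        carriers[bit] = ((m >> bit) & 1).sum(axis=0)
    pis = snp & ((carriers >= 2).sum(axis=0) >= 2)

    # modal genotype-pattern count per column (patterns = bitmask values 1..15)
    max_pattern = np.zeros(m.shape[1], dtype=np.int64)
    for v in range(1, 16):
        np.maximum(max_pattern, (m == v).sum(axis=0), out=max_pattern)
    singleton = snp & (n_present >= 2) & (max_pattern == n_present - 1)

    return {
        "snp": snp,
        "pis": pis,
        "singleton": singleton,
        "n_missing": m.shape[0] - n_present,
    }


def assembly_stats(assembly: Assembly) -> AssemblyStats:
    """Summary statistics over the implied concatenated sample x site matrix.

    A cell is missing when the sample lacks the locus or carries N/-; the
    denominator of ``pct_missing`` is roster size x total bp.
    """
    n_snps = n_pis = n_sing = 0
    missing_cells = 0
    n_roster = len(assembly.roster)
    for loc in assembly.loci:
        cls = classify_columns(loc)
        n_snps += int(cls["snp"].sum())
        n_pis += int(cls["pis"].sum())
        n_sing += int(cls["singleton"].sum())
        missing_cells += int(cls["n_missing"].sum())
        missing_cells += (n_roster - len(loc.samples)) * loc.length
    total = n_roster * assembly.total_bp
    pct = 100.0 * missing_cells / total if total else 0.0
    return AssemblyStats(assembly.n_loci, assembly.total_bp, n_snps, n_pis, n_sing, pct)


def filter_min_taxon_coverage(assembly: Assembly, frac: float) -> Assembly:
    """Retain loci carried by at least ``frac`` of the roster (inclusive >=)."""
    if not assembly.roster:
        raise ValueError("empty roster")
    if not 0.0 < frac <= 1.0:
        raise ValueError(f"min taxon coverage fraction must be in (0, 1], got {frac}")
    n = len(assembly.roster)
    loci = [loc for loc in assembly.loci if len(loc.samples) / n >= frac]
    config = dict(assembly.config)
    config["min_taxon_coverage"] = frac
    return Assembly(loci, list(assembly.roster), config)


def concatenate(assembly: Assembly) -> tuple[dict[str, str], list[tuple[str, int, int]]]:
    """Build the supermatrix over the roster plus a 1-based partition table.

    Absent sample x locus blocks are filled with ``N``.
    """
    parts: list[tuple[str, int, int]] = []
    chunks: dict[str, list[str]] = {s: [] for s in assembly.roster}
    pos = 0
    for loc in assembly.loci:
        parts.append((loc.locus_id, pos + 1, pos + loc.length))
        pos += loc.length
        for s in assembly.roster:
            chunks[s].append(loc.samples.get(s, "N" * loc.length))
    return {s: "".join(c) for s, c in chunks.items()}, parts


# ---------------------------------------------------------------------------
# .loci dialect I/O

_LOCUS_TERM = re.compile(r"^//(?P<marks>.*?)\|(?P<id>[^|]*)\|?\s*$")


def _marker_line(locus: LocusAlignment, name_width: int) -> str:
    cls = classify_columns(locus)
    marks = np.full(locus.length, " ", dtype="<U1")
    marks[cls["snp"]] = "-"
    marks[cls["pis"]] = "*"
    return "//" + " " * (name_width - 2) + "".join(marks) + f"|{locus.locus_id}|"


def write_loci(assembly: Assembly, path) -> None:
    """Write the assembly in the ``.loci`` dialect."""
    with open(path, "w") as fh:
        for locus in assembly.loci:
            width = max(len(s) for s in locus.samples) + 2
            for name, seq in locus.samples.items():
                fh.write(f">{name}" + " " * (width - len(name)) + seq + "\n")
            fh.write(_marker_line(locus, width + 1) + "\n")


def read_loci(path, roster: list[str] | None = None, config: dict | None = None) -> Assembly:
    """Parse a ``.loci`` file.

    The roster defaults to all samples seen, in order of first appearance.
    Ragged blocks and unknown characters raise :class:`LociParseError` naming
    the offending locus / site.
    """
    loci: list[LocusAlignment] = []
    seen: dict[str, None] = {}
    samples: dict[str, str] = {}
    n_blocks = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            term = _LOCUS_TERM.match(line)
            if term:
                n_blocks += 1
                locus_id = term.group("id").strip() or str(n_blocks)
                if not samples:
                    raise LociParseError(f"locus {locus_id}: empty block")
                loci.append(LocusAlignment(locus_id, samples))
                samples = {}
            elif line.startswith(">"):
                name, _, seq = line[1:].partition(" ")
                name = name.strip()
                seq = seq.strip().upper()
                bad = set(seq) - VALID_CHARS
                if bad:
                    site = next(i for i, c in enumerate(seq) if c in bad) + 1
                    raise LociParseError(
                        f"sample {name}, block {n_blocks + 1}: unknown character "
                        f"{sorted(bad)[0]!r} at site {site}"
                    )
                samples[name] = seq
                seen.setdefault(name, None)
            else:
                raise LociParseError(f"unparseable line: {line!r}")
    if samples:
        raise LociParseError("unterminated final locus block")
    return Assembly(loci, roster if roster is not None else list(seen), config or {})


# ---------------------------------------------------------------------------
# auxiliary formats


def write_fasta_loci(assembly: Assembly, out_dir) -> list[str]:
    """Write one FASTA alignment per locus; returns the file paths."""
    import os

    paths = []
    for loc in assembly.loci:
        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in loc.samples.items()
        ]
        p = os.path.join(out_dir, f"locus_{loc.locus_id}.fasta")
        SeqIO.write(records, p, "fasta")
        paths.append(p)
    return paths


def read_fasta_locus(path, locus_id: str | None = None) -> LocusAlignment:
    records = list(SeqIO.parse(path, "fasta"))
    import os

    if locus_id is None:
        locus_id = os.path.splitext(os.path.basename(path))[0]
    return LocusAlignment(locus_id, {r.id: str(r.seq).upper() for r in records})


def write_phylip(assembly: Assembly, path) -> None:
    """Relaxed PHYLIP supermatrix (absent blocks N-filled)."""
    matrix, _ = concatenate(assembly)
    width = assembly.total_bp
    with open(path, "w") as fh:
        fh.write(f"{len(assembly.roster)} {width}\n")
        for name in assembly.roster:
            fh.write(f"{name}  {matrix[name]}\n")


def write_partitions(assembly: Assembly, path) -> None:
    """RAxML-style partition table, 1-based inclusive ranges."""
    _, parts = concatenate(assembly)
    with open(path, "w") as fh:
        for locus_id, start, end in parts:
            fh.write(f"DNA, {locus_id} = {start}-{end}\n")


def stats_row(assembly: Assembly) -> dict:
    """One report row with the standard assembly-table column names."""
    st = assembly_stats(assembly)
    row = {
        "Number of bp": st.total_bp,
        "Number of loci": st.n_loci,
        "Number of SNPs": st.n_snps,
        "Number of PIS": st.n_pis,
        "Number of singleton sites": st.n_singletons,
        "Percentage of missing data": round(st.pct_missing, 2),
    }
    return row
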