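"""Ground-truthed synthetic GBS assemblies.

The generator emulates the statistical structure a replicate-based error
analysis assumes: a Yule species tree, Jukes-Cantor locus alignments with
diploid heterozygosity, and replicate pairs whose copies are independently
corrupted by locus dropout, per-locus sequence miscalls, heterozygote
collapse and genotype swaps.  Every corruption event is logged, so error
statistics computed downstream are exactly recoverable from the log.

Two injection regimes are supported: independent per-copy probabilities
(closed-form expectations; e.g. locus error -> 2d/(1+d) for dropout
probability d) and an exact-count mode that plants a requested number of
events into replicate-A copies only, at distinct loci/sites, so that event
counts equal observable counts.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .iupac import BASES, consensus_char
from .loci import Assembly, LocusAlignment, classify_columns

_IDX = {b: i for i, b in enumerate(BASES)}


# ---------------------------------------------------------------------------
# species tree


def simulate_species_tree(n_taxa: int, birth_rate: float = 1.0, seed: int = 0) -> dendropy.Tree:
    """Pure-birth (Yule) ultrametric species tree with ``n_taxa`` tips.

    Lineages split at per-lineage rate ``birth_rate`` starting from the crown
    (two lineages at time 0); after the tree holds ``n_taxa`` lineages one
    further exponential waiting time is appended, so the expected crown age is
    sum_{k=2..n} 1/(k*birth_rate).  Deterministic for a fixed seed.
    """
    if n_taxa < 2:
        raise ValueError(f"n_taxa must be >= 2, got {n_taxa}")
    if birth_rate <= 0:
        raise ValueError(f"birth_rate must be > 0, got {birth_rate}")
    rng = np.random.default_rng(seed)

    tree = dendropy.Tree()
    tree.is_rooted = True
    root = tree.seed_node
    birth: dict[dendropy.Node, float] = {}
    active: list[dendropy.Node] = []
    t = 0.0
    for _ in range(2):
        child = dendropy.Node()
        root.add_child(child)
        birth[child] = 0.0
        active.append(child)
    while len(active) < n_taxa:
        k = len(active)
        t += rng.exponential(1.0 / (birth_rate * k))
        node = active.pop(rng.integers(k))
        node.edge.length = t - birth[node]
        for _ in range(2):
            child = dendropy.Node()
            node.add_child(child)
            birth[child] = t
            active.append(child)
    t += rng.exponential(1.0 / (birth_rate * n_taxa))
    for node in active:
        node.edge.length = t - birth[node]

    # deterministic tip labels in left-to-right order
    ns = tree.taxon_namespace
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon = ns.new_taxon(label=f"t{i}")
    root.edge.length = None
    return tree


def is_ultrametric(tree: dendropy.Tree, tol: float = 1e-9) -> bool:
    depths = []
    for leaf in tree.leaf_node_iter():
        d = 0.0
        node = leaf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        depths.append(d)
    return max(depths) - min(depths) <= tol


# ---------------------------------------------------------------------------
# sequence evolution


@dataclass
class TrueLocus:
    locus_id: str
    length: int
    alleles: dict[str, tuple[str, str]]  # taxon -> ordered diploid allele pair


@dataclass
class TrueGenotypes:
    """Ground-truth diploid genotypes that a GBS pipeline output approximates."""

    taxa: list[str]
    loci: list[TrueLocus]
    mu: float
    het: float
    seed: int

    def consensus(self, taxon: str, locus: TrueLocus) -> str:
        a, b = locus.alleles[taxon]
        return "".join(consensus_char(x, y) for x, y in zip(a, b))


def _decode(arr: np.ndarray) -> str:
    return "".join(BASES[i] for i in arr)


def evolve_loci(
    tree: dendropy.Tree,
    n_loci: int,
    locus_length: int,
    mu: float,
    het: float = 0.0,
    seed: int = 0,
) -> TrueGenotypes:
    """Evolve ``n_loci`` alignments on ``tree`` under Jukes-Cantor.

    Branch lengths are multiplied by ``mu`` to give expected substitutions per
    site; the per-branch change probability is (3/4)(1 - exp(-4/3 * mu * b)).
    Heterozygosity is injected per taxon by mutating one allele copy at
    Bernoulli(``het``) sites.  Deterministic for a fixed seed.
    """
    if n_loci < 1 or locus_length < 1:
        raise ValueError("n_loci and locus_length must be >= 1")
    if not 0.0 <= het <= 1.0:
        raise ValueError(f"het must be in [0, 1], got {het}")
    if mu < 0:
        raise ValueError(f"mu must be >= 0, got {mu}")
    rng = np.random.default_rng(seed)
    taxa = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    loci: list[TrueLocus] = []
    for li in range(n_loci):
        seqs: dict[int, np.ndarray] = {}
        tip_seq: dict[str, np.ndarray] = {}
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                seqs[id(node)] = rng.integers(0, 4, size=locus_length)
                continue
            parent = seqs[id(node.parent_node)].copy()
            b = (node.edge.length or 0.0) * mu
            p_change = 0.75 * (1.0 - np.exp(-4.0 * b / 3.0))
            mask = rng.random(locus_length) < p_change
            n = int(mask.sum())
            if n:
                parent[mask] = (parent[mask] + rng.integers(1, 4, size=n)) % 4
            seqs[id(node)] = parent
            if node.is_leaf():
                tip_seq[node.taxon.label] = parent
        alleles: dict[str, tuple[str, str]] = {}
        for taxon in taxa:
            a1 = tip_seq[taxon]
            a2 = a1.copy()
            mask = rng.random(locus_length) < het
            n = int(mask.sum())
            if n:
                a2[mask] = (a2[mask] + rng.integers(1, 4, size=n)) % 4
            alleles[taxon] = (_decode(a1), _decode(a2))
        loci.append(TrueLocus(str(li + 1), locus_length, alleles))
    return TrueGenotypes(taxa, loci, mu, het, seed)


# ---------------------------------------------------------------------------
# corruption


@dataclass(frozen=True)
class ExactCounts:
    """Exact numbers of events planted into replicate-A copies."""

    k_drop: int = 0
    k_allele: int = 0
    m_het: int = 0
    m_hard: int = 0


@dataclass(frozen=True)
class ErrorSpec:
    """Error processes applied independently per replicate copy.

    dropout:       probability a copy loses a whole locus
    seq_error:     probability a retained locus copy acquires one random
                   substitution at a uniformly chosen site
    het_collapse:  probability per heterozygous site that the genotype
                   collapses to one of its alleles (heterozygous-class error)
    geno_swap:     probability per true SNP site that the genotype is replaced
                   by a homozygote disjoint from it (hard-class error)
    """

    dropout: float = 0.0
    seq_error: float = 0.0
    het_collapse: float = 0.0
    geno_swap: float = 0.0
    exact: ExactCounts | None = None

    def __post_init__(self) -> None:
        for name in ("dropout", "seq_error", "het_collapse", "geno_swap"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.exact is not None:
            for name in ("k_drop", "k_allele", "m_het", "m_hard"):
                if getattr(self.exact, name) < 0:
                    raise ValueError(f"exact count {name} must be >= 0")


@dataclass(frozen=True)
class SnpEvent:
    replicate_id: str
    locus_id: str
    site: int  # 0-based
    old: str
    new: str
    event_class: str  # "het" | "hard"


@dataclass
class CorruptionLog:
    """Every injected corruption event, for exact downstream recovery."""

    dropped: list[tuple[str, str]] = field(default_factory=list)
    seq_corrupted: list[tuple[str, str]] = field(default_factory=list)
    snp_events: list[SnpEvent] = field(default_factory=list)

    @property
    def n_dropped(self) -> int:
        return len(self.dropped)

    @property
    def n_seq_corrupted(self) -> int:
        return len(self.seq_corrupted)

    def n_snp(self, event_class: str) -> int:
        return sum(1 for e in self.snp_events if e.event_class == event_class)

    def write_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["event_class", "replicate_id", "locus_id", "site_1based", "old", "new"])
            for rep, loc in self.dropped:
                w.writerow(["dropout", rep, loc, "", "", ""])
            for rep, loc in self.seq_corrupted:
                w.writerow(["seq", rep, loc, "", "", ""])
            for e in self.snp_events:
                w.writerow([e.event_class, e.replicate_id, e.locus_id, e.site + 1, e.old, e.new])


def _consensus_array(truth: TrueGenotypes, taxon: str, locus: TrueLocus) -> list[str]:
    a, b = locus.alleles[taxon]
    return [consensus_char(x, y) for x, y in zip(a, b)]


def _true_snp_columns(truth: TrueGenotypes) -> dict[str, np.ndarray]:
    """0-based variable-column indices per locus over all true allele copies."""
    out = {}
    for locus in truth.loci:
        samples = {}
        for taxon, (a, b) in locus.alleles.items():
            samples[taxon + "/1"] = a
            samples[taxon + "/2"] = b
        cls = classify_columns(LocusAlignment(locus.locus_id, samples))
        out[locus.locus_id] = np.nonzero(cls["snp"])[0]
    return out


def corrupt_assembly(
    truth: TrueGenotypes,
    spec: ErrorSpec,
    pairing: list[tuple[str, str, str]],
    seed: int = 0,
    background_dropout: float = 0.0,
) -> tuple[Assembly, CorruptionLog]:
    """Emit a replicate-containing assembly with injected, logged errors.

    Each ``(sample, rep_a, rep_b)`` pairing entry replaces the sample with two
    independently corrupted copies; non-replicated taxa pass through
    uncorrupted (unless ``background_dropout`` > 0, which applies locus
    dropout — but no genotyping errors — to them, for missing-data realism).
    In exact-count mode all events go into the first pair's A copy, at
    distinct loci/sites, so counts are observable one-to-one.
    """
    paired = {s: (ra, rb) for s, ra, rb in pairing}
    missing = set(paired) - set(truth.taxa)
    if missing:
        raise ValueError(f"pairing samples not in truth: {sorted(missing)}")
    rep_ids = [r for _, ra, rb in pairing for r in (ra, rb)]
    if len(set(rep_ids)) != len(rep_ids):
        raise ValueError("replicate ids must be distinct")
    rng = np.random.default_rng(seed)

    log = CorruptionLog()
    # sample -> locus_id -> consensus char list (missing locus = absent key)
    out: dict[str, dict[str, list[str]]] = {}
    roster: list[str] = []
    copies: list[tuple[str, str, bool]] = []  # (taxon, emitted name, corrupted?)
    for taxon in truth.taxa:
        if taxon in paired:
            ra, rb = paired[taxon]
            copies.append((taxon, ra, True))
            copies.append((taxon, rb, True))
            roster.extend([ra, rb])
        else:
            copies.append((taxon, taxon, False))
            roster.append(taxon)

    if spec.exact is not None:
        _corrupt_exact(truth, spec.exact, pairing, rng, out, copies, log)
    else:
        _corrupt_probabilistic(truth, spec, rng, out, copies, log)

    if background_dropout > 0.0:
        for taxon, name, corrupted in copies:
            if corrupted:
                continue
            for locus in truth.loci:
                if rng.random() < background_dropout:
                    out[name].pop(locus.locus_id, None)

    loci = []
    for locus in truth.loci:
        samples = {
            name: "".join(out[name][locus.locus_id])
            for name in roster
            if locus.locus_id in out[name]
        }
        if samples:
            loci.append(LocusAlignment(locus.locus_id, samples))
    return Assembly(loci, roster, {"seed": seed}), log


def _substitute(seq: list[str], site: int, rng: np.random.Generator) -> tuple[str, str]:
    from .iupac import allele_set

    old = seq[site]
    choices = [b for b in BASES if b not in allele_set(old)]
    new = choices[rng.integers(len(choices))]
    seq[site] = new
    return old, new


def _corrupt_probabilistic(truth, spec, rng, out, copies, log) -> None:
    snp_cols = None
    if spec.geno_swap > 0:
        snp_cols = _true_snp_columns(truth)
    for taxon, name, corrupted in copies:
        out[name] = {}
        for locus in truth.loci:
            if corrupted and rng.random() < spec.dropout:
                log.dropped.append((name, locus.locus_id))
                continue
            a1, a2 = locus.alleles[taxon]
            geno = [(x, y) for x, y in zip(a1, a2)]
            if corrupted:
                if spec.het_collapse > 0:
                    for i, (x, y) in enumerate(geno):
                        if x != y and rng.random() < spec.het_collapse:
                            keep = (x, y)[rng.integers(2)]
                            log.snp_events.append(
                                SnpEvent(name, locus.locus_id, i,
                                         consensus_char(x, y), keep, "het")
                            )
                            geno[i] = (keep, keep)
                if spec.geno_swap > 0:
                    for i in snp_cols[locus.locus_id]:
                        x, y = geno[i]
                        if rng.random() < spec.geno_swap:
                            choices = [b for b in BASES if b not in (x, y)]
                            new = choices[rng.integers(len(choices))]
                            log.snp_events.append(
                                SnpEvent(name, locus.locus_id, int(i),
                                         consensus_char(x, y), new, "hard")
                            )
                            geno[i] = (new, new)
            seq = [consensus_char(x, y) for x, y in geno]
            if corrupted and spec.seq_error > 0 and rng.random() < spec.seq_error:
                site = int(rng.integers(locus.length))
                _substitute(seq, site, rng)
                log.seq_corrupted.append((name, locus.locus_id))
            out[name][locus.locus_id] = seq


def _corrupt_exact(truth, counts: ExactCounts, pairing, rng, out, copies, log) -> None:
    target_rep = pairing[0][1]  # replicate-A of the first pair
    target_taxon = pairing[0][0]
    n_loci = len(truth.loci)

    if counts.k_drop + counts.k_allele > n_loci:
        raise ValueError("exact counts exceed available loci")
    order = rng.permutation(n_loci)
    drop_ids = {truth.loci[i].locus_id for i in order[: counts.k_drop]}
    allele_ids = {
        truth.loci[i].locus_id
        for i in order[counts.k_drop : counts.k_drop + counts.k_allele]
    }
    snp_pool = [
        truth.loci[i] for i in order[counts.k_drop + counts.k_allele :]
    ]

    # pick distinct sites for het / hard injections in the remaining loci
    het_sites: list[tuple[TrueLocus, int]] = []
    hard_sites: list[tuple[TrueLocus, int]] = []
    if counts.m_het or counts.m_hard:
        available = []
        for locus in snp_pool:
            a1, a2 = locus.alleles[target_taxon]
            for i in range(locus.length):
                available.append((locus, i, a1[i] != a2[i]))
        het_avail = [(l, i) for l, i, h in available if h]
        if counts.m_het > len(het_avail):
            raise ValueError(
                f"m_het={counts.m_het} exceeds {len(het_avail)} heterozygous sites"
            )
        idx = rng.permutation(len(het_avail))[: counts.m_het]
        het_sites = [het_avail[i] for i in idx]
        used = set((l.locus_id, i) for l, i in het_sites)
        hard_avail = [(l, i) for l, i, _ in available if (l.locus_id, i) not in used]
        if counts.m_hard > len(hard_avail):
            raise ValueError(f"m_hard={counts.m_hard} exceeds available sites")
        idx = rng.permutation(len(hard_avail))[: counts.m_hard]
        hard_sites = [hard_avail[i] for i in idx]

    het_by_locus: dict[str, list[int]] = {}
    for locus, i in het_sites:
        het_by_locus.setdefault(locus.locus_id, []).append(i)
    hard_by_locus: dict[str, list[int]] = {}
    for locus, i in hard_sites:
        hard_by_locus.setdefault(locus.locus_id, []).append(i)

    for taxon, name, corrupted in copies:
        out[name] = {}
        injected = corrupted and name == target_rep
        for locus in truth.loci:
            if injected and locus.locus_id in drop_ids:
                log.dropped.append((name, locus.locus_id))
                continue
            a1, a2 = locus.alleles[taxon]
            geno = [(x, y) for x, y in zip(a1, a2)]
            if injected:
                for i in het_by_locus.get(locus.locus_id, []):
                    x, y = geno[i]
                    keep = (x, y)[rng.integers(2)]
                    log.snp_events.append(
                        SnpEvent(name, locus.locus_id, i,
                                 consensus_char(x, y), keep, "het")
                    )
                    geno[i] = (keep, keep)
                for i in hard_by_locus.get(locus.locus_id, []):
                    x, y = geno[i]
                    choices = [b for b in BASES if b not in (x, y)]
                    new = choices[rng.integers(len(choices))]
                    log.snp_events.append(
                        SnpEvent(name, locus.locus_id, i,
                                 consensus_char(x, y), new, "hard")
                    )
                    geno[i] = (new, new)
            seq = [consensus_char(x, y) for x, y in geno]
            if injected and locus.locus_id in allele_ids:
                site = int(rng.integers(locus.length))
                _substitute(seq, site, rng)
                log.seq_corrupted.append((name, locus.locus_id))
            out[name][locus.locus_id] = seq


# ---------------------------------------------------------------------------
# read-level quality filter


def quality_filter_reads(
    reads: list[tuple[str, list[int]]],
    q_min: int = 20,
    max_n_frac: float = 0.04,
) -> list[str]:
    """Mask low-quality bases and drop N-heavy reads.

    Bases with quality < ``q_min`` become N; reads whose N fraction exceeds
    ``max_n_frac`` (strictly) are discarded.  Read order is preserved.
    """
    out = []
    for idx, (bases, quals) in enumerate(reads):
        if len(bases) != len(quals):
            raise ValueError(
                f"read {idx}: {len(quals)} quality scores for {len(bases)} bases"
            )
        masked = "".join(
            "N" if q < q_min else b for b, q in zip(bases, quals)
        )
        if bases and masked.count("N") / len(masked) > max_n_frac:
            continue
        out.append(masked)
    return out
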