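"""Synthetic inputs with known ground truth.

This module fabricates everything the pipeline consumes — a reference
sequence, a multi-population variant panel with planted per-class mutation
intensity multipliers, annotation tracks, sample metadata, and a signature
catalog — so that every downstream operation can be tested against the
planted truth.

The generator's model of a panel is deliberately simple: each variant is
attributed to a generating population (chosen in proportion to sample
counts), its mutation class is drawn with probability proportional to
(admissible reference sites for the class's context) x (the population's
class multiplier), and it is placed at a uniformly chosen admissible site,
so the reference context always matches the class. Carriers are then
assigned according to the frequency source: a fixed derived-allele count
(the f2 doubleton regime by default, with a configurable probability of a
single homozygote versus two heterozygotes), or allele counts drawn from a
coalescent site frequency spectrum (constant size or exponential growth).
What is deliberately absent: linkage disequilibrium, phasing, sequencing
error — none of the downstream statistics depend on them.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seq import BASES, PYRIMIDINES, complement, reverse_complement
from .coalescent_sim import GrowthModel, aggregate_sfs
from .io import Reference, VariantPanel, canonical_contexts
from .variant_spectrum import CLASSES, CLASS_LABELS

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticGenomeSpec",
    "PopulationSpec",
    "TrackSpec",
    "generate_reference",
    "generate_panel",
    "generate_tracks",
    "random_strand_intervals",
    "decile_track_from_score",
    "random_methylation_sites",
    "synthetic_catalog",
]


# ---------------------------------------------------------------------------
# Reference sequence
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    """Parameters of a synthetic reference chromosome.

    ``cpg_boost`` multiplies the probability of G following C (then
    renormalizes), so 0 yields a CpG-free genome and 1 an i.i.d. one.
    """

    length: int
    base_weights: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    cpg_boost: float = 1.0
    seed: int = 0
    chrom: str = "chr1"

    def __post_init__(self) -> None:
        if self.length < 3:
            raise ValueError("genome length must be at least 3")
        w = np.asarray(self.base_weights, dtype=float)
        if w.shape != (4,) or (w < 0).any():
            raise ValueError("base_weights must be 4 non-negative reals")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("base_weights must sum to 1")
        if self.cpg_boost < 0:
            raise ValueError("cpg_boost must be non-negative")


def generate_reference(spec: SyntheticGenomeSpec) -> tuple[Reference, pd.Series]:
    """Generate a reference sequence and its canonical trinucleotide
    frequency table (32 pyrimidine-centered contexts)."""
    rng = np.random.default_rng(spec.seed)
    w = np.asarray(spec.base_weights, dtype=float)
    if spec.cpg_boost == 1.0:
        codes = rng.choice(4, size=spec.length, p=w)
    else:
        # first-order Markov chain: after a C, the G weight is multiplied
        after_c = w.copy()
        after_c[2] *= spec.cpg_boost
        if after_c.sum() == 0:
            raise ValueError("cpg_boost and base_weights leave no base after C")
        after_c /= after_c.sum()
        cum_default = np.cumsum(w)
        cum_after_c = np.cumsum(after_c)
        u = rng.random(spec.length)
        codes = np.empty(spec.length, dtype=np.int64)
        prev = -1
        for i in range(spec.length):
            cum = cum_after_c if prev == 1 else cum_default
            prev = int(np.searchsorted(cum, u[i], side="right"))
            codes[i] = prev
    seq = "".join(np.array(list(BASES))[codes])
    ref = Reference({spec.chrom: seq})
    return ref, ref.trinucleotide_frequencies()


# ---------------------------------------------------------------------------
# Variant panel
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PopulationSpec:
    """One population of a panel, with planted per-class multipliers."""

    name: str
    region: str
    n_samples: int
    class_multipliers: dict[str, float] = field(default_factory=dict)
    growth: GrowthModel | None = None
    source: str = "tissue"

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("population needs at least one sample")
        if any(m <= 0 for m in self.class_multipliers.values()):
            raise ValueError("class multipliers must be strictly positive")
        if self.source not in ("cell_line", "tissue"):
            raise ValueError("source must be cell_line or tissue")
        unknown = set(self.class_multipliers) - set(CLASS_LABELS)
        if unknown:
            raise ValueError(f"unknown class labels in multipliers: {sorted(unknown)}")


_CODE = {b: i for i, b in enumerate(BASES)}


def _context_site_index(reference: Reference) -> dict[str, list[tuple[str, np.ndarray, np.ndarray]]]:
    """Positions (1-based, middle base) admitting each canonical context.

    Returns context -> list of (chrom, positions, flipped) where ``flipped``
    marks sites whose reference triplet is the reverse complement of the
    canonical context (pyrimidine on the - strand)."""
    contexts = canonical_contexts()
    ctx_index = {c: i for i, c in enumerate(contexts)}
    canon = np.full(64, -1, dtype=np.int64)
    flip = np.zeros(64, dtype=bool)
    for code in range(64):
        tri = BASES[code // 16] + BASES[(code // 4) % 4] + BASES[code % 4]
        if tri[1] in PYRIMIDINES:
            canon[code] = ctx_index[tri]
        else:
            canon[code] = ctx_index[reverse_complement(tri)]
            flip[code] = True
    out: dict[str, list[tuple[str, np.ndarray, np.ndarray]]] = {c: [] for c in contexts}
    lut = np.full(256, -1, dtype=np.int64)
    for b, i in _CODE.items():
        lut[ord(b)] = i
    for chrom, seq in reference.sequences.items():
        if len(seq) < 3:
            continue
        codes = lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
        valid = codes >= 0
        tri = codes[:-2] * 16 + codes[1:-1] * 4 + codes[2:]
        ok = valid[:-2] & valid[1:-1] & valid[2:]
        for c in contexts:
            sel = ok & (canon[np.where(ok, tri, 0)] == ctx_index[c])
            pos = np.flatnonzero(sel) + 2  # 1-based position of the middle base
            if pos.size:
                out[c].append((chrom, pos, flip[tri[sel]]))
    return out


def generate_panel(
    reference: Reference,
    populations: list[PopulationSpec],
    n_variants: int,
    freq_source: str = "fixed_f",
    seed: int = 0,
    *,
    target_f: int = 2,
    hom_prob: float = 0.1,
    lowercase_aa_fraction: float = 0.0,
    class_cross_fraction: dict[str, float] | None = None,
    growth: GrowthModel | None = None,
    sfs_trees: int = 300,
) -> tuple[VariantPanel, dict]:
    """Generate a variant panel with planted spectrum differences.

    ``freq_source`` is "fixed_f" (every variant has derived-allele count
    ``target_f``) or "coalescent" (counts drawn from a simulated site
    frequency spectrum — constant size, or under ``growth`` — and carriers
    spread uniformly over all haplotypes). ``class_cross_fraction`` plants,
    per class label, a probability that a doubleton's second heterozygote is
    drawn from a *different* population, emulating cross-population repeat
    mutations. A ``lowercase_aa_fraction`` of records get a lowercase
    (low-confidence) ancestral-allele annotation to exercise the downstream
    filtering rule.

    Returns the panel plus a truth record of everything planted.
    """
    if not populations:
        raise ValueError("need at least one population")
    if n_variants < 0:
        raise ValueError("n_variants must be non-negative")
    rng = np.random.default_rng(seed)
    class_cross_fraction = class_cross_fraction or {}

    # sample metadata
    rows = []
    pop_slices: list[np.ndarray] = []
    k = 0
    for pop in populations:
        center = rng.uniform(-60, 60), rng.uniform(-180, 180)
        idx = np.arange(k, k + pop.n_samples)
        pop_slices.append(idx)
        for i in range(pop.n_samples):
            rows.append(
                {
                    "sample": f"{pop.name}_{i:03d}",
                    "population": pop.name,
                    "region": pop.region,
                    "source": pop.source,
                    "latitude": round(center[0] + rng.normal(0, 2), 4),
                    "longitude": round(center[1] + rng.normal(0, 2), 4),
                }
            )
        k += pop.n_samples
    samples = pd.DataFrame(rows)
    n_tot = len(samples)

    # admissible sites per context, consumed in random order without reuse
    site_index = _context_site_index(reference)
    pools: dict[str, list] = {}
    cursors: dict[str, int] = {}
    for ctx, chunks in site_index.items():
        sites = [(chrom, int(p), bool(f)) for chrom, pos, flipped in chunks for p, f in zip(pos, flipped)]
        order = rng.permutation(len(sites))
        pools[ctx] = [sites[i] for i in order]
        cursors[ctx] = 0
    n_sites_ctx = {c: len(pools[c]) for c in pools}

    # per-population class probabilities: context abundance x multiplier
    base_w = np.array([n_sites_ctx[c.context] for c in CLASSES], dtype=float)
    skipped_classes: dict[str, list[str]] = {}
    pop_probs = []
    for pop in populations:
        mult = np.array([pop.class_multipliers.get(lbl, 1.0) for lbl in CLASS_LABELS])
        w = base_w * mult
        absent = [
            lbl
            for lbl in pop.class_multipliers
            if n_sites_ctx[CLASSES[CLASS_LABELS.index(lbl)].context] == 0
        ]
        if absent:
            skipped_classes[pop.name] = absent
            warnings.warn(
                f"population {pop.name}: requested class(es) {absent} have no "
                "admissible reference sites; skipped"
            )
        if w.sum() == 0:
            raise ValueError("no admissible sites for any mutation class")
        pop_probs.append(w / w.sum())

    # allele-count distribution for the coalescent frequency source
    if freq_source == "coalescent":
        n_hap = 2 * n_tot
        sfs = aggregate_sfs(
            n_hap,
            sfs_trees,
            growth=growth,
            kinds=("single",),
            seed=int(rng.integers(2**31)),
        )["single"]
        freq_probs = sfs.proportions()
    elif freq_source != "fixed_f":
        raise ValueError(f"unknown freq_source {freq_source!r}")

    # allocate variants to generating populations by sample count
    pop_weights = np.array([p.n_samples for p in populations], dtype=float)
    pop_of_variant = rng.choice(len(populations), size=n_variants, p=pop_weights / pop_weights.sum())

    var_rows = []
    genos = []
    planted_counts = np.zeros((len(populations), 96), dtype=np.int64)
    n_truncated = 0
    for p_i, pop in enumerate(populations):
        m = int((pop_of_variant == p_i).sum())
        if m == 0:
            continue
        class_counts = rng.multinomial(m, pop_probs[p_i])
        for c_i in np.flatnonzero(class_counts):
            mclass = CLASSES[c_i]
            need = int(class_counts[c_i])
            ctx = mclass.context
            pool, cur = pools[ctx], cursors[ctx]
            take = min(need, len(pool) - cur)
            if take < need:
                n_truncated += need - take
                logger.warning(
                    "context %s exhausted: %d variant(s) dropped", ctx, need - take
                )
            for chrom, pos, flipped in pool[cur : cur + take]:
                anc = complement(mclass.ancestral) if flipped else mclass.ancestral
                der = complement(mclass.derived) if flipped else mclass.derived
                aa = anc.lower() if rng.random() < lowercase_aa_fraction else anc
                g = _draw_genotypes(
                    rng,
                    n_tot,
                    pop_slices[p_i],
                    freq_source,
                    target_f,
                    hom_prob,
                    class_cross_fraction.get(mclass.label, 0.0),
                    freq_probs if freq_source == "coalescent" else None,
                )
                var_rows.append((chrom, pos, anc, der, aa))
                genos.append(g)
                planted_counts[p_i, c_i] += 1
            cursors[ctx] = cur + take

    if var_rows:
        variants = pd.DataFrame(var_rows, columns=["chrom", "pos", "ref", "alt", "aa"])
        genotypes = np.vstack(genos)
        order = np.lexsort((variants["pos"].to_numpy(), variants["chrom"].to_numpy()))
        variants = variants.iloc[order].reset_index(drop=True)
        genotypes = genotypes[order]
    else:
        variants = pd.DataFrame(columns=["chrom", "pos", "ref", "alt", "aa"])
        genotypes = np.zeros((0, n_tot), dtype=np.int8)

    panel = VariantPanel(variants, genotypes, samples)
    truth = {
        "seed": seed,
        "n_variants_requested": n_variants,
        "n_variants_realized": int(len(variants)),
        "n_truncated": n_truncated,
        "freq_source": freq_source,
        "target_f": target_f,
        "hom_prob": hom_prob,
        "lowercase_aa_fraction": lowercase_aa_fraction,
        "class_cross_fraction": dict(class_cross_fraction),
        "growth": (
            {"fold": growth.fold, "onset": growth.onset, "rate": growth.rate}
            if growth
            else None
        ),
        "skipped_classes": skipped_classes,
        "populations": [
            {
                "name": pop.name,
                "region": pop.region,
                "n_samples": pop.n_samples,
                "source": pop.source,
                "class_multipliers": dict(pop.class_multipliers),
                "planted_class_counts": {
                    CLASS_LABELS[c]: int(planted_counts[i, c])
                    for c in np.flatnonzero(planted_counts[i])
                },
            }
            for i, pop in enumerate(populations)
        ],
    }
    return panel, truth


def _draw_genotypes(
    rng: np.random.Generator,
    n_tot: int,
    pop_idx: np.ndarray,
    freq_source: str,
    target_f: int,
    hom_prob: float,
    cross_fraction: float,
    freq_probs: np.ndarray | None,
) -> np.ndarray:
    g = np.zeros(n_tot, dtype=np.int8)
    if freq_source == "coalescent":
        k = int(rng.choice(len(freq_probs), p=freq_probs)) + 1
        haps = rng.choice(2 * n_tot, size=k, replace=False)
        np.add.at(g, haps // 2, 1)
        return g
    f = target_f
    n_p = len(pop_idx)
    if f == 1:
        g[rng.choice(pop_idx)] = 1
        return g
    if f == 2:
        if rng.random() < hom_prob or (n_p == 1 and cross_fraction == 0.0):
            g[rng.choice(pop_idx)] = 2
            return g
        first = rng.choice(pop_idx)
        if cross_fraction > 0 and n_tot > n_p and rng.random() < cross_fraction:
            outside = np.setdiff1d(np.arange(n_tot), pop_idx, assume_unique=True)
            second = rng.choice(outside)
        else:
            others = pop_idx[pop_idx != first]
            second = rng.choice(others)
        g[first] = 1
        g[second] = 1
        return g
    if f > 2 * n_p:
        raise ValueError(f"cannot place {f} derived copies in {n_p} diploid samples")
    haps = rng.choice(2 * n_p, size=f, replace=False)
    np.add.at(g, pop_idx[haps // 2], 1)
    return g


# ---------------------------------------------------------------------------
# Annotation tracks
# ---------------------------------------------------------------------------

_TRACK_KINDS = ("strand", "methylation", "decile")
_STRAND_LABELS = {"+", "-", "both", "none"}


@dataclass(frozen=True)
class TrackSpec:
    """A BED-like annotation track: half-open intervals with labels."""

    kind: str
    intervals: tuple[tuple[str, int, int, str], ...]

    def __post_init__(self) -> None:
        if self.kind not in _TRACK_KINDS:
            raise ValueError(f"unknown track kind {self.kind!r}")
        for chrom, start, end, label in self.intervals:
            if start < 0 or end < start:
                raise ValueError(f"bad interval {chrom}:{start}-{end}")
            if self.kind == "strand" and label not in _STRAND_LABELS:
                raise ValueError(f"bad strand label {label!r}")
            if self.kind == "decile" and not (str(label).isdigit() and 0 <= int(label) <= 9):
                raise ValueError(f"bad decile label {label!r}")


def _flatten_strand(intervals) -> list[tuple[str, int, int, str]]:
    """Sweep-line flattening: positions covered by both + and - transcripts
    are labeled "both"; uncovered positions are simply absent."""
    by_chrom: dict[str, list] = {}
    for chrom, start, end, label in intervals:
        by_chrom.setdefault(chrom, []).append((start, end, label))
    out = []
    for chrom, ivs in by_chrom.items():
        events: dict[int, list[tuple[str, int]]] = {}
        for start, end, label in ivs:
            if start == end:
                continue
            events.setdefault(start, []).append((label, +1))
            events.setdefault(end, []).append((label, -1))
        depth = {"+": 0, "-": 0}
        prev = None
        for b in sorted(events):
            if prev is not None and b > prev:
                label = _strand_label(depth)
                if label != "none":
                    out.append((chrom, prev, b, label))
            for label, d in events[b]:
                if label in depth:
                    depth[label] += d
            prev = b
    # merge adjacent intervals with equal labels
    merged: list[tuple[str, int, int, str]] = []
    for iv in sorted(out):
        if merged and merged[-1][0] == iv[0] and merged[-1][2] == iv[1] and merged[-1][3] == iv[3]:
            merged[-1] = (iv[0], merged[-1][1], iv[2], iv[3])
        else:
            merged.append(iv)
    return merged


def _strand_label(depth: dict[str, int]) -> str:
    plus, minus = depth["+"] > 0, depth["-"] > 0
    if plus and minus:
        return "both"
    if plus:
        return "+"
    if minus:
        return "-"
    return "none"


def generate_tracks(
    reference: Reference, specs: list[TrackSpec], seed: int = 0
) -> dict[str, list[tuple[str, int, int, str]]]:
    """Validate and materialize tracks; strand tracks are flattened so that
    overlapping +/- transcription resolves to "both"."""
    out: dict[str, list[tuple[str, int, int, str]]] = {}
    for spec in specs:
        for chrom, start, end, _ in spec.intervals:
            if chrom not in reference.sequences:
                raise ValueError(f"interval on unknown chromosome {chrom!r}")
            if end > len(reference.sequences[chrom]):
                raise ValueError(f"interval {chrom}:{start}-{end} beyond genome end")
        if spec.kind == "strand":
            out[spec.kind] = _flatten_strand(spec.intervals)
        else:
            out[spec.kind] = sorted(spec.intervals)
    return out


def write_bed(intervals, path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, label in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{label}\n")


def read_bed(path) -> list[tuple[str, int, int, str]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, start, end, label = line.split()[:4]
            out.append((chrom, int(start), int(end), label))
    return out


def random_strand_intervals(
    reference: Reference, n_genes: int, mean_length: int, seed: int = 0
) -> TrackSpec:
    """Random gene-like intervals with random strands (may overlap)."""
    rng = np.random.default_rng(seed)
    ivs = []
    for chrom, seq in reference.sequences.items():
        L = len(seq)
        for _ in range(n_genes):
            length = max(1, int(rng.exponential(mean_length)))
            start = int(rng.integers(0, max(1, L - length)))
            ivs.append((chrom, start, min(start + length, L), rng.choice(["+", "-"])))
    return TrackSpec("strand", tuple(ivs))


def decile_track_from_score(
    reference: Reference, bin_size: int, scores: np.ndarray | None = None, seed: int = 0
) -> TrackSpec:
    """Assign each ``bin_size`` block a decile (0-9) of a per-bin score; with
    no score supplied a smooth synthetic one is generated."""
    rng = np.random.default_rng(seed)
    ivs = []
    for chrom, seq in reference.sequences.items():
        n_bins = (len(seq) + bin_size - 1) // bin_size
        if scores is None:
            x = np.linspace(0, 8 * np.pi, n_bins)
            s = np.sin(x) + 0.3 * rng.normal(size=n_bins) + np.linspace(0, 1, n_bins)
        else:
            s = np.asarray(scores, dtype=float)
            if len(s) != n_bins:
                raise ValueError(f"need {n_bins} scores for {chrom}, got {len(s)}")
        deciles = pd.qcut(pd.Series(s).rank(method="first"), 10, labels=False)
        for b in range(n_bins):
            start = b * bin_size
            ivs.append((chrom, start, min(start + bin_size, len(seq)), str(int(deciles[b]))))
    return TrackSpec("decile", tuple(ivs))


def random_methylation_sites(
    reference: Reference, n_high: int, n_low: int, seed: int = 0
) -> tuple[list[tuple[str, int]], list[tuple[str, int]]]:
    """Disjoint high- and low-methylation site lists drawn from CpG
    cytosines (1-based positions of the C of + strand CG dinucleotides)."""
    rng = np.random.default_rng(seed)
    cpg: list[tuple[str, int]] = []
    for chrom, seq in reference.sequences.items():
        for i in range(len(seq) - 1):
            if seq[i] == "C" and seq[i + 1] == "G":
                cpg.append((chrom, i + 1))
    if n_high + n_low > len(cpg):
        raise ValueError(f"only {len(cpg)} CpG sites available")
    chosen = rng.choice(len(cpg), size=n_high + n_low, replace=False)
    high = [cpg[i] for i in chosen[:n_high]]
    low = [cpg[i] for i in chosen[n_high:]]
    return high, low


def synthetic_catalog(
    n_signatures: int, seed: int = 0, sparsity: float = 0.85
) -> pd.DataFrame:
    """A synthetic stand-in for a somatic-signature catalog: ``n_signatures``
    sparse non-negative 96-vectors, each normalized to sum 1, indexed by
    class label. (Synthetic — not derived from any real tumor catalog.)"""
    rng = np.random.default_rng(seed)
    W = rng.gamma(0.5, size=(96, n_signatures))
    mask = rng.random((96, n_signatures)) < sparsity
    W[mask] *= 0.05
    W /= W.sum(axis=0, keepdims=True)
    return pd.DataFrame(
        W,
        index=list(CLASS_LABELS),
        columns=[f"synthetic_{i + 1}" for i in range(n_signatures)],
    )
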