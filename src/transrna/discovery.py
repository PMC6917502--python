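"""Genome-free discovery of haustorially-induced small RNAs (HI-sRNAs).

The discovery chain, which needs no parasite genome assembly:

1. ``size_filter`` — keep reads of 20-24 nt (the sizes of plant miRNAs/siRNAs).
2. ``condense`` — greedy abundance-ranked clustering of sequencing-error /
   variant clouds within a small Levenshtein radius; clusters below an RPM
   floor are discarded.
3. ``host_filter`` — remove sRNAs attributable to the host plant rather than
   the parasite (similar to a host miRNA, perfectly matching host sequence,
   or abundant in non-parasitized control libraries).
4. ``call_hi_srnas`` — negative-binomial differential-accumulation test of
   interface vs parasite stem with Benjamini-Hochberg control; significant
   up-regulated sRNAs are the HI-sRNAs.

Reads-per-million (RPM) denominators are the per-library totals of the
size-filtered read population, computed before host filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import edlib
import numpy as np
from scipy import stats

from .seq_io import SequenceRecord, reverse_complement

#: Variance floor for the method-of-moments NB dispersion estimate.
DISPERSION_FLOOR = 0.01


def levenshtein(a: str, b: str, limit: int | None = None) -> int:
    """Levenshtein edit distance; with ``limit`` the true distance is reported
    only when <= limit (edlib returns -1 beyond the band, mapped to limit+1)."""
    k = -1 if limit is None else limit
    d = edlib.align(a, b, task="distance", k=k)["editDistance"]
    if d == -1:
        return (limit or 0) + 1
    return d


def size_filter(records: Sequence[SequenceRecord], min_len: int = 20, max_len: int = 24) -> list[SequenceRecord]:
    """Retain reads with min_len <= length <= max_len, preserving order."""
    return [r for r in records if min_len <= len(r.seq) <= max_len]


def library_totals(records: Sequence[SequenceRecord]) -> dict[str, int]:
    """Per-library read totals, the RPM denominator population."""
    totals: dict[str, int] = {}
    for rec in records:
        for lib, n in (rec.counts or {}).items():
            totals[lib] = totals.get(lib, 0) + n
    return totals


@dataclass
class CondensedSRNA:
    """A representative sRNA with the combined abundance of its variant cloud."""

    representative_seq: str
    members: set[str]
    counts: dict[str, int]
    rpm: dict[str, float] = field(default_factory=dict)

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())

    @property
    def max_rpm(self) -> float:
        return max(self.rpm.values()) if self.rpm else 0.0


def _rank_order(records: Sequence[SequenceRecord]) -> list[SequenceRecord]:
    # decreasing total count, ties broken lexicographically by sequence
    return sorted(records, key=lambda r: (-r.total_count, r.seq))


def condense(
    records: Sequence[SequenceRecord],
    condense_dist: int = 2,
    rpm_min: float = 0.5,
    totals: Mapping[str, int] | None = None,
) -> list[CondensedSRNA]:
    """Greedy abundance-ranked condensation of unique reads into variant clusters.

    Sequences are visited in decreasing total-count order (ties lexicographic).
    A sequence within ``condense_dist`` edits of an already-accepted
    representative joins the highest-ranked such representative; otherwise it
    seeds a new cluster. After the pass, clusters whose combined abundance
    (max RPM over libraries) is below ``rpm_min`` are discarded.

    ``totals`` supplies the RPM denominators; by default the totals of
    ``records`` themselves (the size-filtered population).
    """
    if not records:
        return []
    libs = sorted({lib for r in records for lib in (r.counts or {})})
    if not libs:
        raise ValueError("condense requires per-library counts")
    if totals is None:
        totals = library_totals(records)
    clusters: list[CondensedSRNA] = []
    for rec in _rank_order(records):
        home = None
        for cluster in clusters:  # clusters are in rank order of their seeds
            if levenshtein(rec.seq, cluster.representative_seq, limit=condense_dist) <= condense_dist:
                home = cluster
                break
        if home is None:
            clusters.append(
                CondensedSRNA(
                    representative_seq=rec.seq,
                    members={rec.seq},
                    counts={lib: (rec.counts or {}).get(lib, 0) for lib in libs},
                )
            )
        else:
            home.members.add(rec.seq)
            for lib in libs:
                home.counts[lib] += (rec.counts or {}).get(lib, 0)
    kept = []
    for cluster in clusters:
        cluster.rpm = {
            lib: 1e6 * cluster.counts[lib] / totals[lib] if totals.get(lib) else 0.0
            for lib in libs
        }
        if cluster.max_rpm >= rpm_min:
            kept.append(cluster)
    return kept


# ---------------------------------------------------------------------------
# Host filtering


class HostSequenceIndex:
    """Exact full-length substring lookup against host genome/transcriptome
    sequences, on either strand."""

    def __init__(self, sequences: Sequence[str]):
        self._seqs = [s.upper() for s in sequences]

    def contains(self, query: str) -> bool:
        rc = reverse_complement(query)
        return any(query in s or rc in s for s in self._seqs)


def _mean_rpm(cluster: CondensedSRNA, libs: Sequence[str]) -> float:
    if not libs:
        return 0.0
    return float(np.mean([cluster.rpm.get(lib, 0.0) for lib in libs]))


def host_filter(
    condensed: Sequence[CondensedSRNA],
    host_mirnas: Sequence[SequenceRecord],
    host_index: HostSequenceIndex,
    control_libs: Sequence[str],
    parasite_libs: Sequence[str],
    host_mirna_dist: int = 2,
) -> list[CondensedSRNA]:
    """Remove host-derived sRNAs. An sRNA is dropped if ANY rule fires:

    1. within ``host_mirna_dist`` edits of an annotated host miRNA;
    2. exact full-length substring of a host sequence on either strand;
    3. mean control-library RPM exceeds 1/100 of its mean parasite-library RPM
       (zero parasite signal with any control signal also drops it).
    """
    kept = []
    for cluster in condensed:
        if any(
            levenshtein(cluster.representative_seq, m.seq, limit=host_mirna_dist) <= host_mirna_dist
            for m in host_mirnas
        ):
            continue
        if host_index.contains(cluster.representative_seq):
            continue
        control = _mean_rpm(cluster, control_libs)
        parasite = _mean_rpm(cluster, parasite_libs)
        if parasite == 0.0:
            if control > 0.0:
                continue
        elif control > parasite / 100.0:
            continue
        kept.append(cluster)
    return kept


# ---------------------------------------------------------------------------
# Differential accumulation (NB Wald test, DESeq-style normalization)


@dataclass
class HISRNA:
    """A condensed sRNA called significantly interface-up-regulated."""

    condensed: CondensedSRNA
    log2fc: float
    padj: float
    isolate_id: str = ""

    @property
    def representative_seq(self) -> str:
        return self.condensed.representative_seq


def median_of_ratios(counts: np.ndarray) -> np.ndarray:
    """DESeq-style size factors: median across features of the ratio to the
    per-feature geometric mean, using features positive in every library."""
    counts = np.asarray(counts, dtype=float)
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        return np.ones(counts.shape[1])
    log_counts = np.log(counts[positive])
    log_geomean = log_counts.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(log_counts - log_geomean, axis=0))
    return np.where(factors > 0, factors, 1.0)


def nb_wald_test(
    counts: np.ndarray,
    group_a: Sequence[int],
    group_b: Sequence[int],
    dispersion_floor: float = DISPERSION_FLOOR,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature NB Wald test of group_a vs group_b (columns of ``counts``).

    Returns (log2 fold change a/b, two-sided p-value). Library depth is
    normalized by median-of-ratios size factors; the per-feature dispersion is
    a pooled method-of-moments estimate under Var = mu + alpha*mu^2, floored.
    """
    counts = np.asarray(counts, dtype=float)
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each condition needs >= 2 replicate libraries")
    factors = median_of_ratios(counts)
    norm = counts / factors
    a, b = norm[:, list(group_a)], norm[:, list(group_b)]
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    # pooled MoM dispersion: average excess variance over both conditions
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_a = (a.var(axis=1, ddof=1) - mean_a) / mean_a**2
        alpha_b = (b.var(axis=1, ddof=1) - mean_b) / mean_b**2
    alpha = np.nanmean(np.stack([alpha_a, alpha_b]), axis=0)
    alpha = np.where(np.isfinite(alpha), alpha, dispersion_floor)
    alpha = np.maximum(alpha, dispersion_floor)
    pseudo = 0.5
    log2fc = np.log2((mean_a + pseudo) / (mean_b + pseudo))
    # delta method on log2 of the replicate-mean under NB sampling
    var_mean_a = (mean_a + alpha * mean_a**2) / a.shape[1]
    var_mean_b = (mean_b + alpha * mean_b**2) / b.shape[1]
    se2 = (var_mean_a / (mean_a + pseudo) ** 2 + var_mean_b / (mean_b + pseudo) ** 2) / np.log(2) ** 2
    se = np.sqrt(se2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / se, 0.0)
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    both_zero = (mean_a == 0) & (mean_b == 0)
    pvals = np.where(both_zero, 1.0, pvals)
    return log2fc, pvals


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """BH adjusted p-values (step-up)."""
    pvals = np.asarray(pvals, dtype=float)
    n = len(pvals)
    if n == 0:
        return pvals
    order = np.argsort(pvals, kind="stable")
    ranked = pvals[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def call_hi_srnas(
    condensed: Sequence[CondensedSRNA],
    interface_libs: Sequence[str],
    stem_libs: Sequence[str],
    fdr: float = 0.1,
    isolate_id: str = "",
) -> list[HISRNA]:
    """Call haustorially-induced sRNAs: NB Wald test of interface vs stem,
    BH correction across all tested sRNAs, keep padj < fdr with log2fc > 0."""
    if len(interface_libs) < 2 or len(stem_libs) < 2:
        raise ValueError("each condition needs >= 2 replicate libraries")
    if not condensed:
        return []
    libs = list(interface_libs) + list(stem_libs)
    counts = np.array([[c.counts.get(lib, 0) for lib in libs] for c in condensed], dtype=float)
    idx_interface = list(range(len(interface_libs)))
    idx_stem = list(range(len(interface_libs), len(libs)))
    log2fc, pvals = nb_wald_test(counts, idx_interface, idx_stem)
    padj = benjamini_hochberg(pvals)
    calls = [
        HISRNA(condensed=c, log2fc=float(fc), padj=float(p), isolate_id=isolate_id)
        for c, fc, p in zip(condensed, log2fc, padj)
        if p < fdr and fc > 0
    ]
    calls.sort(key=lambda h: (h.padj, -h.log2fc, h.representative_seq))
    return calls
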