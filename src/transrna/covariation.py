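"""Covariation between sRNA superfamily variation and target-site variation.

The headline statistic of the pipeline: positions where a superfamily of
sRNAs varies tend to be exactly the positions where homologous target sites
vary across host species — largely synonymous codon positions, which gives
superfamily variation a three-nucleotide period. Per-position variability is
measured as Shannon entropy (bits) on alignment columns; sRNA positions are
mapped antiparallel onto sense-strand target columns; and an ordinary least
squares regression of sRNA entropy on target entropy quantifies covariation
(slope, Pearson r, and the regression t-test p-value, R ``lm`` convention).

Also here: 8-amino-acid sliding-window conservation of target regions
(target sites fall in unusually conserved windows) and gene-family motif
discovery (clustering translated high-stringency target sites).
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import edlib
import numpy as np
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq
from scipy import stats

from .seq_io import TranscriptAnnotation
from .targeting import TargetInteraction, scan_targets

logger = logging.getLogger("transrna")

GAP = "-"

_CODON_TO_AA: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_TO_AA[_stop] = "*"


@dataclass
class HomologSet:
    """In-frame homologous target-site sequences (site plus flanks) across
    species, all anchored to the same coordinates."""

    target_id: str
    sequences: dict[str, str]  # species id -> nucleotide sequence
    site_start: int  # 0-based half-open site interval within the sequences
    site_end: int
    frame_offset: int = 0  # of site_start within its codon

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError(f"{self.target_id}: homolog sequences must be equal length")
        if lengths and not 0 <= self.site_start < self.site_end <= lengths.pop():
            raise ValueError(f"{self.target_id}: site interval outside sequences")

    def site_columns(self) -> list[str]:
        """Sense-strand alignment columns of the site region."""
        rows = list(self.sequences.values())
        return ["".join(row[i] for row in rows) for i in range(self.site_start, self.site_end)]


def column_entropy(column: str, alphabet: str | None = None) -> float:
    """Shannon entropy (bits) of one alignment column; gaps are excluded.

    Raises ValueError when fewer than two non-gap symbols remain.
    """
    symbols = [c for c in column.upper() if c != GAP]
    if len(symbols) < 2:
        raise ValueError("column has fewer than 2 non-gap symbols")
    if alphabet is not None:
        bad = set(symbols) - set(alphabet.upper())
        if bad:
            raise ValueError(f"symbols {sorted(bad)} outside alphabet")
    total = len(symbols)
    return -sum(
        (n / total) * math.log2(n / total) for n in Counter(symbols).values()
    )


def synonymous_count(codon: str, position: int) -> int:
    """Number of nucleotides (including the current one) that preserve the
    encoded amino acid when substituted at ``position`` (0, 1, or 2) of
    ``codon`` under the standard genetic code. Stop codons are scored against
    the stop 'residue'."""
    codon = codon.upper().replace("U", "T")
    if len(codon) != 3 or set(codon) - set("ACGT"):
        raise ValueError(f"need an unambiguous codon, got {codon!r}")
    if position not in (0, 1, 2):
        raise ValueError("position must be 0, 1, or 2")
    aa = _CODON_TO_AA[codon]
    count = 0
    for base in "ACGT":
        mutant = codon[:position] + base + codon[position + 1 :]
        if _CODON_TO_AA[mutant] == aa:
            count += 1
    return count


def translate_codons(seq: str) -> str:
    """Translate an in-frame nucleotide sequence (stops rendered ``*``)."""
    return str(Seq(seq).translate())


# ---------------------------------------------------------------------------
# Window conservation


@dataclass
class WindowConservation:
    """Sliding-window mean entropy of an amino-acid alignment."""

    window_values: list[float]  # one mean entropy per window start
    window: int
    target_start: int | None
    target_value: float | None
    other_median: float
    other_q25: float
    other_q75: float


def window_conservation(
    aa_alignment: Sequence[str],
    window: int = 8,
    target_start: int | None = None,
) -> WindowConservation:
    """Mean column entropy of every ``window``-residue window (step 1).

    ``target_start`` flags the window corresponding to the target site; the
    summary reports its value next to the median and 25/75% quartiles of all
    *other* windows.
    """
    length = len(aa_alignment[0])
    if any(len(row) != length for row in aa_alignment):
        raise ValueError("alignment rows must have equal length")
    if window > length:
        raise ValueError(f"window {window} longer than alignment {length}")
    entropies = [
        column_entropy("".join(row[i] for row in aa_alignment)) for i in range(length)
    ]
    values = [
        float(np.mean(entropies[s : s + window])) for s in range(length - window + 1)
    ]
    target_value = None
    others = values
    if target_start is not None:
        if not 0 <= target_start < len(values):
            raise ValueError("target window start outside alignment")
        target_value = values[target_start]
        others = [v for i, v in enumerate(values) if i != target_start]
    q25, med, q75 = (
        (np.percentile(others, [25, 50, 75]) if others else (0.0, 0.0, 0.0))
    )
    return WindowConservation(
        window_values=values,
        window=window,
        target_start=target_start,
        target_value=target_value,
        other_median=float(med),
        other_q25=float(q25),
        other_q75=float(q75),
    )


# ---------------------------------------------------------------------------
# Covariation regression


@dataclass
class CovariationResult:
    """Paired positional-entropy profiles and their regression summary."""

    srna_entropy: list[float]  # by sRNA position (5'->3')
    target_entropy: list[float]  # same order, mapped antiparallel
    slope: float
    pearson_r: float
    p_value: float
    n: int
    degenerate: bool = False  # zero variance in either profile


def antiparallel_map(srna_len: int, site_start: int, site_end: int) -> list[int]:
    """Sense-strand target column paired to each sRNA position 1..L:
    position i pairs column ``site_end - i``."""
    if site_end - site_start < srna_len:
        raise ValueError("site shorter than sRNA")
    return [site_end - i for i in range(1, srna_len + 1)]


def covariation_test(
    superfamily_msa: Sequence[str],
    homologs: HomologSet,
    drop_invariant: bool = False,
) -> CovariationResult:
    """OLS regression of per-position superfamily entropy on homolog target
    entropy, positions paired antiparallel.

    Entropy-undefined columns (fewer than two non-gap symbols) are dropped
    from n. ``drop_invariant`` additionally drops positions invariant in both
    alignments. A superfamily or site with zero entropy variance yields a
    degenerate "no variation" result with p = 1.
    """
    width = len(superfamily_msa[0])
    if any(len(row) != width for row in superfamily_msa):
        raise ValueError("superfamily MSA rows must have equal length")
    if len(superfamily_msa) < 2:
        raise ValueError("superfamily MSA needs >= 2 members")
    site_cols = homologs.site_columns()
    mapping = antiparallel_map(width, homologs.site_start, homologs.site_end)
    xs, ys = [], []
    for i in range(1, width + 1):
        srna_col = "".join(row[i - 1] for row in superfamily_msa)
        target_col = site_cols[mapping[i - 1] - homologs.site_start]
        try:
            y = column_entropy(srna_col)
            x = column_entropy(target_col)
        except ValueError:
            continue
        if drop_invariant and x == 0.0 and y == 0.0:
            continue
        xs.append(x)
        ys.append(y)
    if len(xs) < 3:
        raise ValueError("fewer than 3 paired positions with defined entropy")
    x_arr, y_arr = np.array(xs), np.array(ys)
    if x_arr.std() == 0.0 or y_arr.std() == 0.0:
        return CovariationResult(ys, xs, 0.0, 0.0, 1.0, len(xs), degenerate=True)
    fit = stats.linregress(x_arr, y_arr)
    return CovariationResult(
        srna_entropy=ys,
        target_entropy=xs,
        slope=float(fit.slope),
        pearson_r=float(fit.rvalue),
        p_value=float(fit.pvalue),
        n=len(xs),
    )


# ---------------------------------------------------------------------------
# Gene-family motif discovery


@dataclass
class MotifCluster:
    """Translated target sites of one superfamily grouped by peptide similarity."""

    seed_peptide: str
    members: list[tuple[str, TargetInteraction]] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.members)


def _aa_distance(a: str, b: str) -> int:
    return edlib.align(a, b, task="distance")["editDistance"]


def greedy_peptide_clusters(
    peptides: Sequence[str], max_dist: int = 3
) -> list[list[int]]:
    """Greedy clustering of peptides in descending frequency order of the
    distinct peptides (ties lexicographic): each peptide joins the first seed
    within ``max_dist`` amino-acid edits, else founds a new cluster. Returns
    index groups into ``peptides``."""
    freq = Counter(peptides)
    order = sorted(set(peptides), key=lambda p: (-freq[p], p))
    seeds: list[str] = []
    assignment: dict[str, int] = {}
    for pep in order:
        home = None
        for idx, seed in enumerate(seeds):
            if _aa_distance(pep, seed) <= max_dist:
                home = idx
                break
        if home is None:
            seeds.append(pep)
            home = len(seeds) - 1
        assignment[pep] = home
    groups: list[list[int]] = [[] for _ in seeds]
    for i, pep in enumerate(peptides):
        groups[assignment[pep]].append(i)
    return [g for g in groups if g]


def site_peptide(hit: TargetInteraction, annotation: TranscriptAnnotation) -> str | None:
    """Translate the codons overlapping a target site in its CDS frame.

    Returns None (with a log entry) when the site is not fully inside the CDS.
    """
    if hit.site_start < annotation.cds_start or hit.site_end > annotation.cds_end:
        logger.info(
            "site %s:%d-%d spans CDS boundary, skipped",
            hit.transcript_id, hit.site_start, hit.site_end,
        )
        return None
    offset = (hit.site_start - annotation.cds_start) % 3
    codon_start = hit.site_start - offset
    codon_end = hit.site_end + (-(hit.site_end - annotation.cds_start) % 3)
    codon_end = min(codon_end, annotation.cds_end)
    return translate_codons(annotation.seq[codon_start:codon_end])


def discover_family_motifs(
    member_seqs: Sequence[str],
    annotations: Mapping[str, TranscriptAnnotation],
    motif_score: float = 3.0,
    aa_cluster_dist: int = 3,
    core_start: int = 2,
    core_end: int = 13,
) -> list[MotifCluster]:
    """Find gene-family motifs targeted by a superfamily: scan each member at
    high stringency (score <= ``motif_score``), translate every in-CDS site,
    and greedily cluster the peptides."""
    transcripts = {tid: ann.seq for tid, ann in annotations.items()}
    # one site = one cleavage position: overlapping windows (bulge variants of
    # the same duplex) collapse to their best-scoring window
    best: dict[tuple[str, str, int], TargetInteraction] = {}
    for srna in dict.fromkeys(member_seqs):
        for hit in scan_targets(srna, transcripts, motif_score, core_start, core_end):
            key = (hit.srna_seq, hit.transcript_id, hit.predicted_cut)
            if key not in best or hit.score < best[key].score:
                best[key] = hit
    peptides: list[str] = []
    hits: list[TargetInteraction] = []
    for key in sorted(best):
        hit = best[key]
        pep = site_peptide(hit, annotations[hit.transcript_id])
        if pep is None:
            continue
        peptides.append(pep)
        hits.append(hit)
    clusters = []
    for group in greedy_peptide_clusters(peptides, aa_cluster_dist):
        freq = Counter(peptides[i] for i in group)
        seed = sorted(freq, key=lambda p: (-freq[p], p))[0]
        clusters.append(
            MotifCluster(seed_peptide=seed, members=[(peptides[i], hits[i]) for i in group])
        )
    clusters.sort(key=lambda c: (-c.size, c.seed_peptide))
    return clusters
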