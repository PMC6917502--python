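"""Confirmation of predicted sRNA targets by two independent evidence channels.

Channel A — secondary siRNAs: a targeting event (especially by a 22-nt sRNA)
can trigger production of phased secondary siRNAs from the target mRNA. A
gene locus confirms a prediction when it is significantly up-regulated in
interface vs control stem sRNA libraries AND (1) carries a predicted site of
complementarity score <= 6, (2) its sRNAs come from both strands, (3) their
predominant length is 21/22 nt, (4) it has >= 20 reads.

Channel B — degradome 5'-end peaks: sRNA-guided cleavage leaves mRNA 5' ends
at the position paired to guide positions 10/11. A predicted interaction
confirms when (1) score <= 6, (2) the site starts > 100 nt into the
transcript (away from the transcription start site), (3) the transcript is
not organellar, (4) the pooled peak exceeds the median occupied-position
depth of that transcript, (5) the peak is present in every treatment
replicate, and (6) the peak is >= 10-fold over control stems (pseudo-count
0.5 when the control is empty; the control filter can be disabled when no
control libraries exist).

The two channels are computed independently; "confirmed by both" is their
set intersection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .seq_io import DegradomeProfile, LocusAlignmentSummary, TranscriptAnnotation
from .targeting import TargetInteraction

PHASE_LENGTH = 21


# ---------------------------------------------------------------------------
# Secondary-siRNA channel


@dataclass
class LocusStats:
    """Summary of small-RNA accumulation at one gene locus."""

    gene_id: str
    depth: int
    plus_fraction: float
    size_histogram: dict[int, int]
    predominant_sizes: set[int]
    up_regulated: bool
    padj: float = 1.0

    @classmethod
    def from_summaries(
        cls,
        summaries: Sequence[LocusAlignmentSummary],
        gene_id: str,
        up_regulated: bool = False,
        padj: float = 1.0,
    ) -> "LocusStats":
        reads = [r for s in summaries if s.gene_id == gene_id for r in s.reads]
        depth = len(reads)
        plus = sum(1 for r in reads if r.strand == "+")
        hist: dict[int, int] = {}
        for r in reads:
            hist[r.length] = hist.get(r.length, 0) + 1
        top = max(hist.values()) if hist else 0
        predominant = {length for length, n in hist.items() if n == top and top > 0}
        return cls(
            gene_id=gene_id,
            depth=depth,
            plus_fraction=plus / depth if depth else 0.0,
            size_histogram=hist,
            predominant_sizes=predominant,
            up_regulated=up_regulated,
            padj=padj,
        )


@dataclass
class LocusCall:
    """Filter-by-filter outcome for one locus/prediction pair.

    ``passes`` order: [site score, unstranded, predominant 21/22-nt size,
    minimum depth]; ``confirmed`` additionally requires up-regulation.
    """

    gene_id: str
    interaction: TargetInteraction | None
    passes: list[bool]
    up_regulated: bool

    @property
    def confirmed(self) -> bool:
        return self.up_regulated and all(self.passes)


def secondary_sirna_confirm(
    locus_stats: Mapping[str, LocusStats],
    predictions: Sequence[TargetInteraction],
    transcript_genes: Mapping[str, str],
    confirm_score: float = 6.0,
    unstranded_min: float = 0.2,
    unstranded_max: float = 0.8,
    min_depth: int = 20,
) -> list[LocusCall]:
    """Apply the secondary-siRNA locus criteria to every up-regulated locus.

    ``transcript_genes`` maps prediction transcript ids to gene ids. A
    prediction naming a gene absent from ``locus_stats`` raises KeyError.
    """
    by_gene: dict[str, list[TargetInteraction]] = {}
    for hit in predictions:
        gene = transcript_genes.get(hit.transcript_id)
        if gene is None:
            raise KeyError(f"prediction references unknown transcript {hit.transcript_id!r}")
        by_gene.setdefault(gene, []).append(hit)
    calls = []
    for gene_id, stats in locus_stats.items():
        hits = sorted(by_gene.get(gene_id, []), key=lambda h: h.score)
        best = hits[0] if hits else None
        passes = [
            best is not None and best.score <= confirm_score,
            unstranded_min <= stats.plus_fraction <= unstranded_max,
            bool(stats.predominant_sizes & {21, 22}),
            stats.depth >= min_depth,
        ]
        calls.append(LocusCall(gene_id, best, passes, stats.up_regulated))
    return calls


# ---------------------------------------------------------------------------
# Phasing


@dataclass
class PhasingProfile:
    """Distribution of read 5' ends over the 21-nt phase registers downstream
    of a cleavage site (register 1 = in phase with the cut)."""

    register_counts: list[int]
    in_phase_fraction: float


def phasing_profile(
    positions: Sequence[int], cut_pos: int, phase_length: int = PHASE_LENGTH
) -> PhasingProfile:
    """Assign each read 5'-end position to its phase register relative to the
    predicted cut: register = ((pos - cut) mod phase_length) + 1."""
    if len(positions) == 0:
        raise ValueError("phasing_profile requires at least one read")
    counts = [0] * phase_length
    for pos in positions:
        counts[(pos - cut_pos) % phase_length] += 1
    return PhasingProfile(counts, counts[0] / len(positions))


# ---------------------------------------------------------------------------
# Degradome channel


@dataclass
class PeakCall:
    """Six-filter outcome for one predicted interaction against the degradome."""

    transcript_id: str
    srna_seq: str
    position: int  # predicted cut, 0-based
    replicate_depths: dict[str, int] = field(default_factory=dict)
    control_depth: float = 0.0
    fold_vs_control: float = 0.0
    passes: list[bool] = field(default_factory=list)

    @property
    def confirmed(self) -> bool:
        return all(self.passes)


def _window_depth(profile: DegradomeProfile, pos: int, window: int) -> int:
    return sum(profile.depth.get(p, 0) for p in range(pos - window, pos + window + 1))


def degradome_confirm(
    profiles: Sequence[DegradomeProfile],
    predictions: Sequence[TargetInteraction],
    annotations: Mapping[str, TranscriptAnnotation],
    confirm_score: float = 6.0,
    min_site_start: int = 100,
    fold_threshold: float = 10.0,
    peak_window: int = 0,
    require_control_fold: bool = True,
) -> list[PeakCall]:
    """Apply the six degradome criteria to every predicted interaction.

    Filter order in ``passes``: [score, distance from transcript start,
    non-organellar, peak > median occupied-position depth, peak in all
    treatment replicates, >= ``fold_threshold`` over control]. The peak is
    read at the predicted cut position (+/- ``peak_window`` nt). Pooled
    treatment depth is used for the median comparison; the control depth is
    the mean over control replicates with a 0.5 pseudo-count in the fold
    ratio. With ``require_control_fold=False`` (no control libraries exist)
    filter 6 passes vacuously.
    """
    treatment: dict[str, list[DegradomeProfile]] = {}
    control: dict[str, list[DegradomeProfile]] = {}
    for prof in profiles:
        bucket = treatment if prof.condition == "treatment" else control
        bucket.setdefault(prof.transcript_id, []).append(prof)
    calls = []
    for hit in predictions:
        ann = annotations.get(hit.transcript_id)
        if ann is None:
            raise KeyError(f"transcript {hit.transcript_id!r} missing from annotations")
        reps = treatment.get(hit.transcript_id, [])
        ctrls = control.get(hit.transcript_id, [])
        pos = hit.predicted_cut
        rep_depths = {p.replicate_id: _window_depth(p, pos, peak_window) for p in reps}
        pooled: dict[int, int] = {}
        for p in reps:
            for position, count in p.depth.items():
                pooled[position] = pooled.get(position, 0) + count
        pooled_peak = sum(
            count for position, count in pooled.items() if abs(position - pos) <= peak_window
        )
        occupied = [count for count in pooled.values() if count > 0]
        median_depth = float(np.median(occupied)) if occupied else 0.0
        control_depth = (
            float(np.mean([_window_depth(p, pos, peak_window) for p in ctrls])) if ctrls else 0.0
        )
        # fold ratio uses replicates that detect the peak, so that replicate
        # presence (filter 5) and control enrichment (filter 6) toggle
        # independently
        detected = [d for d in rep_depths.values() if d > 0]
        min_rep = min(detected) if detected else 0
        fold = min_rep / max(control_depth, 0.5)
        passes = [
            hit.score <= confirm_score,
            hit.site_start > min_site_start,
            not ann.organellar,
            pooled_peak > median_depth,
            bool(rep_depths) and all(depth >= 1 for depth in rep_depths.values()),
            (fold >= fold_threshold) if require_control_fold else True,
        ]
        calls.append(
            PeakCall(
                transcript_id=hit.transcript_id,
                srna_seq=hit.srna_seq,
                position=pos,
                replicate_depths=rep_depths,
                control_depth=control_depth,
                fold_vs_control=fold,
                passes=passes,
            )
        )
    return calls


def confirmed_by_both(
    locus_calls: Sequence[LocusCall],
    peak_calls: Sequence[PeakCall],
    transcript_genes: Mapping[str, str],
) -> set[str]:
    """Gene ids confirmed independently by both evidence channels."""
    genes_a = {c.gene_id for c in locus_calls if c.confirmed}
    genes_b = {
        transcript_genes.get(c.transcript_id, c.transcript_id)
        for c in peak_calls
        if c.confirmed
    }
    return genes_a & genes_b
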