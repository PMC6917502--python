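"""Complementarity-based sRNA target prediction (plant-miRNA-style scoring).

An sRNA pairs antiparallel to an mRNA site: sRNA position 1 (5' end) pairs
the 3'-most nucleotide of the site on the sense strand. Each sRNA/target
duplex is scored with position-weighted penalties, lower = stronger:

* mismatch            1.0
* G:U wobble pair     0.5
* bulged nucleotide   1.0 (either strand; at most one single-nt bulge)
* all penalties double when the sRNA position involved lies in the 5' core
  (positions 2..13 from the sRNA 5' end, 1-based, configurable)

``scan_targets`` scores every ungapped transcript window plus all
single-bulge variants and reports interactions at or below a score cutoff.
The predicted cleavage position is the target base paired to sRNA position
10 (cleavage between positions 10 and 11 of the guide).

Sequences are handled in DNA space (U already normalized to T upstream).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .seq_io import reverse_complement

_ENC = str.maketrans("ACGTN", "01234")


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.translate(_ENC).encode(), dtype=np.uint8) - ord("0")


def _penalty_table() -> np.ndarray:
    # rows: sRNA letter, cols: target letter (A C G T N); default mismatch 1.0
    table = np.ones((5, 5))
    complement = {0: 3, 1: 2, 2: 1, 3: 0}  # A-T C-G G-C T-A
    for s, t in complement.items():
        table[s, t] = 0.0
    table[2, 3] = 0.5  # sRNA G : target T(U)
    table[3, 2] = 0.5  # sRNA T(U) : target G
    return table


_PENALTY = _penalty_table()


def pair_state(srna_nt: str, target_nt: str) -> str:
    """Classify one sRNA/target base pair: match, GU, or mismatch."""
    p = _PENALTY[int(_encode(srna_nt)[0]), int(_encode(target_nt)[0])]
    return {0.0: "match", 0.5: "GU", 1.0: "mismatch"}[float(p)]


def position_weights(length: int, core_start: int = 2, core_end: int = 13) -> np.ndarray:
    """Penalty multiplier per sRNA position (1-based core doubles)."""
    w = np.ones(length)
    w[max(core_start - 1, 0) : core_end] = 2.0
    return w


@dataclass(frozen=True)
class PairState:
    """One element of a duplex pairing.

    ``srna_pos`` is 1-based from the sRNA 5' end. For ``bulge_target`` it is
    the anchor position whose weight the bulge penalty takes (the sRNA
    position 5'-adjacent to the insertion point); ``site_index`` is 0-based
    within the site on the sense strand.
    """

    state: str  # match | mismatch | GU | bulge_srna | bulge_target
    srna_pos: int | None
    site_index: int | None


def complementarity_score(
    srna: str,
    site: str,
    pairing: Sequence[PairState],
    core_start: int = 2,
    core_end: int = 13,
) -> float:
    """Score a duplex from its explicit pairing, validating consistency.

    ``site`` is the target region on the sense strand, 5'->3'. Every sRNA
    position must appear exactly once as match/mismatch/GU/bulge_srna; every
    site index exactly once as match/mismatch/GU/bulge_target.
    """
    weights = position_weights(len(srna), core_start, core_end)
    seen_srna: set[int] = set()
    seen_site: set[int] = set()
    score = 0.0
    for ps in pairing:
        if ps.state in ("match", "mismatch", "GU"):
            if ps.srna_pos is None or ps.site_index is None:
                raise ValueError(f"{ps.state} element must name both positions")
            observed = pair_state(srna[ps.srna_pos - 1], site[ps.site_index])
            if observed != ps.state:
                raise ValueError(
                    f"pairing claims {ps.state} at sRNA {ps.srna_pos}/site "
                    f"{ps.site_index} but letters give {observed}"
                )
            seen_srna.add(ps.srna_pos)
            seen_site.add(ps.site_index)
            score += {"match": 0.0, "mismatch": 1.0, "GU": 0.5}[ps.state] * weights[ps.srna_pos - 1]
        elif ps.state == "bulge_srna":
            if ps.srna_pos is None:
                raise ValueError("bulge_srna element must name the sRNA position")
            seen_srna.add(ps.srna_pos)
            score += 1.0 * weights[ps.srna_pos - 1]
        elif ps.state == "bulge_target":
            if ps.srna_pos is None or ps.site_index is None:
                raise ValueError("bulge_target element must name anchor and site index")
            seen_site.add(ps.site_index)
            score += 1.0 * weights[ps.srna_pos - 1]
        else:
            raise ValueError(f"unknown pairing state {ps.state!r}")
    if seen_srna != set(range(1, len(srna) + 1)):
        raise ValueError("pairing does not cover every sRNA position exactly once")
    if seen_site != set(range(len(site))):
        raise ValueError("pairing does not cover every site position exactly once")
    return float(score)


def build_pairing(
    srna: str,
    site: str,
    srna_bulge: int | None = None,
    target_bulge: int | None = None,
) -> list[PairState]:
    """Construct the pairing for a duplex geometry.

    * no bulge: ``len(site) == len(srna)``;
    * ``srna_bulge=j`` (1-based, interior): sRNA position j unpaired,
      ``len(site) == len(srna) - 1``;
    * ``target_bulge=k`` (0-based site index, interior): site position k
      unpaired, ``len(site) == len(srna) + 1``.
    """
    L = len(srna)
    if srna_bulge is not None and target_bulge is not None:
        raise ValueError("at most one bulge per duplex")
    pairing: list[PairState] = []
    if srna_bulge is None and target_bulge is None:
        if len(site) != L:
            raise ValueError("ungapped duplex needs equal lengths")
        for i in range(1, L + 1):
            k = L - i
            pairing.append(PairState(pair_state(srna[i - 1], site[k]), i, k))
    elif srna_bulge is not None:
        j = srna_bulge
        if not 2 <= j <= L - 1:
            raise ValueError("sRNA bulge must be interior")
        if len(site) != L - 1:
            raise ValueError("sRNA-bulge duplex needs site length len(srna) - 1")
        pairing.append(PairState("bulge_srna", j, None))
        for i in range(1, L + 1):
            if i == j:
                continue
            k = (L - 1 - i) if i < j else (L - i)
            pairing.append(PairState(pair_state(srna[i - 1], site[k]), i, k))
    else:
        k0 = target_bulge
        if not 1 <= k0 <= L - 1:  # site indices 0..L, interior only
            raise ValueError("target bulge must be interior")
        if len(site) != L + 1:
            raise ValueError("target-bulge duplex needs site length len(srna) + 1")
        anchor = L - k0  # sRNA position 5'-adjacent to the insertion point
        pairing.append(PairState("bulge_target", anchor, k0))
        for i in range(1, L + 1):
            k = L - i if L - i < k0 else L - i + 1
            pairing.append(PairState(pair_state(srna[i - 1], site[k]), i, k))
    return pairing


@dataclass
class TargetInteraction:
    """One predicted sRNA/transcript interaction."""

    srna_seq: str
    transcript_id: str
    site_start: int  # 0-based half-open on the transcript, sense strand
    site_end: int
    score: float
    pairing: list[PairState]
    predicted_cut: int  # 0-based transcript position

    @property
    def site_length(self) -> int:
        return self.site_end - self.site_start

    def pairing_string(self) -> str:
        """Per-sRNA-position symbols from the 5' end: ``|`` match, ``o`` G:U,
        ``x`` mismatch, ``b`` bulged sRNA nucleotide."""
        symbols = {}
        for ps in self.pairing:
            if ps.state == "bulge_target":
                continue
            symbols[ps.srna_pos] = {"match": "|", "GU": "o", "mismatch": "x", "bulge_srna": "b"}[
                ps.state
            ]
        return "".join(symbols[i] for i in sorted(symbols))


def _cut_position(start: int, L: int, srna_bulge: int | None, target_bulge: int | None) -> int:
    # target base paired to sRNA position 10 (site spans [start, start+span))
    if srna_bulge is None and target_bulge is None:
        return start + L - 10
    if srna_bulge is not None:
        return start + (L - 1 - 10) if srna_bulge > 10 else start + (L - 10)
    k = L - 10
    return start + (k if k < target_bulge else k + 1)


def scan_targets(
    srna: str,
    transcripts: Mapping[str, str] | Sequence[tuple[str, str]],
    max_score: float = 6.0,
    core_start: int = 2,
    core_end: int = 13,
) -> list[TargetInteraction]:
    """Exhaustively score every transcript window (ungapped + all single-bulge
    variants) against ``srna`` and return interactions with score <= max_score,
    sorted ascending by score, then transcript id, then site start."""
    if max_score < 0:
        raise ValueError("max_score must be >= 0")
    items = transcripts.items() if isinstance(transcripts, Mapping) else transcripts
    L = len(srna)
    q = _encode(srna)
    weights = position_weights(L, core_start, core_end)
    hits: list[TargetInteraction] = []
    for tid, tseq in items:
        t = _encode(tseq)
        hits.extend(
            _scan_one(srna, tid, tseq, t, q, weights, max_score, core_start, core_end)
        )
    hits.sort(key=lambda h: (h.score, h.transcript_id, h.site_start, h.site_length))
    return hits


def _scan_one(srna, tid, tseq, t, q, weights, max_score, core_start, core_end):
    L = len(q)
    hits = []
    # per (start, span) window keep the minimal-score pairing:
    # (score, srna_bulge, target_bulge), ties -> earliest bulge position
    best: dict[tuple[int, int], tuple[float, int | None, int | None]] = {}

    def offer(start: int, span: int, score: float, srna_bulge, target_bulge) -> None:
        key = (start, span)
        if key not in best or score < best[key][0]:
            best[key] = (score, srna_bulge, target_bulge)

    def vector_scores(span: int, srna_del: int | None, site_del: int | None, extra: float):
        # penalty of each window of `span` nt; srna_del: 0-based sRNA index to
        # drop; site_del: 0-based within-window index to drop
        if len(t) < span:
            return None
        windows = np.lib.stride_tricks.sliding_window_view(t, span)
        qq = np.delete(q, srna_del) if srna_del is not None else q
        ww = np.delete(weights, srna_del) if srna_del is not None else weights
        site = np.delete(windows, site_del, axis=1) if site_del is not None else windows
        pen = _PENALTY[qq[::-1][None, :], site] * ww[::-1][None, :]
        return pen.sum(axis=1) + extra

    # ungapped
    scores = vector_scores(L, None, None, 0.0)
    if scores is not None:
        for s in np.flatnonzero(scores <= max_score):
            offer(int(s), L, float(scores[s]), None, None)
    # sRNA bulges (interior positions 2..L-1)
    for j in range(2, L):
        scores = vector_scores(L - 1, j - 1, None, float(weights[j - 1]))
        if scores is None:
            continue
        for s in np.flatnonzero(scores <= max_score):
            offer(int(s), L - 1, float(scores[s]), j, None)
    # target bulges (interior site indices 1..L-1)
    for k in range(1, L):
        anchor = L - k
        scores = vector_scores(L + 1, None, k, float(weights[anchor - 1]))
        if scores is None:
            continue
        for s in np.flatnonzero(scores <= max_score):
            offer(int(s), L + 1, float(scores[s]), None, k)
    for (start, span), (_, srna_bulge, target_bulge) in sorted(best.items()):
        site = tseq[start : start + span]
        pairing = build_pairing(srna, site, srna_bulge=srna_bulge, target_bulge=target_bulge)
        score = complementarity_score(srna, site, pairing, core_start, core_end)
        if score <= max_score:
            hits.append(
                TargetInteraction(
                    srna_seq=srna,
                    transcript_id=tid,
                    site_start=start,
                    site_end=start + span,
                    score=score,
                    pairing=pairing,
                    predicted_cut=_cut_position(start, L, srna_bulge, target_bulge),
                )
            )
    return hits


def scan_all(
    srnas: Sequence[str],
    transcripts: Mapping[str, str],
    max_score: float = 6.0,
    core_start: int = 2,
    core_end: int = 13,
) -> list[TargetInteraction]:
    """Scan many sRNAs against a transcriptome."""
    out: list[TargetInteraction] = []
    for srna in srnas:
        out.extend(scan_targets(srna, transcripts, max_score, core_start, core_end))
    out.sort(key=lambda h: (h.score, h.transcript_id, h.site_start, h.srna_seq))
    return out


def interactions_to_frame(hits: Sequence[TargetInteraction]) -> "pd.DataFrame":
    """Tabulate interactions with 1-based display coordinates (columns say so)."""
    import pandas as pd

    rows = [
        {
            "srna_seq": h.srna_seq,
            "transcript_id": h.transcript_id,
            "site_start_1based": h.site_start + 1,
            "site_end_1based": h.site_end,  # inclusive end in display coords
            "score": h.score,
            "predicted_cut_1based": h.predicted_cut + 1,
            "pairing": h.pairing_string(),
        }
        for h in hits
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "srna_seq", "transcript_id", "site_start_1based", "site_end_1based",
            "score", "predicted_cut_1based", "pairing",
        ],
    )
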