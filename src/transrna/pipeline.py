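"""End-to-end orchestration: discovery -> families -> targeting ->
confirmation -> covariation, with a manifest of inputs, outputs, thresholds
and content digests so a run can be audited and resumed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import confirmation, covariation, discovery, families, seq_io, targeting

logger = logging.getLogger("transrna")


class PipelineError(RuntimeError):
    """Raised when a stage is invoked without its upstream artifact."""


@dataclass
class PipelineResult:
    """All stage outputs of one end-to-end run."""

    hi_srnas: dict[str, list[discovery.HISRNA]]  # isolate -> calls
    superfamilies: list[families.Superfamily]
    strict_families: list[families.Superfamily]
    predictions: list[targeting.TargetInteraction]
    locus_calls: list[confirmation.LocusCall]
    peak_calls: list[confirmation.PeakCall]
    confirmed_genes_locus: set[str] = field(default_factory=set)
    confirmed_genes_degradome: set[str] = field(default_factory=set)
    confirmed_both: set[str] = field(default_factory=set)
    phasing: dict[str, confirmation.PhasingProfile] = field(default_factory=dict)
    covariation_results: dict[str, covariation.CovariationResult] = field(default_factory=dict)
    covariation_superfamily: dict[str, str] = field(default_factory=dict)

    def hi_pairs(self) -> set[tuple[str, str]]:
        return {
            (iso, h.representative_seq) for iso, calls in self.hi_srnas.items() for h in calls
        }


def discover_isolate(
    records: Sequence[seq_io.SequenceRecord],
    interface_libs: Sequence[str],
    stem_libs: Sequence[str],
    control_libs: Sequence[str],
    host_mirnas: Sequence[seq_io.SequenceRecord],
    host_index: discovery.HostSequenceIndex,
    config: Mapping[str, object],
    isolate_id: str = "iso1",
) -> list[discovery.HISRNA]:
    """Run the discovery chain for one isolate's libraries."""
    cfg = seq_io.validate_config(dict(config))
    libs = set(interface_libs) | set(stem_libs) | set(control_libs)
    subset = []
    for rec in records:
        counts = {lib: n for lib, n in (rec.counts or {}).items() if lib in libs}
        if counts and any(counts.values()):
            subset.append(seq_io.SequenceRecord(id=rec.id, seq=rec.seq, counts=counts))
    sized = discovery.size_filter(subset, cfg["min_len"], cfg["max_len"])
    if not sized:
        return []
    totals = discovery.library_totals(sized)
    condensed = discovery.condense(sized, cfg["condense_dist"], cfg["rpm_min"], totals)
    parasite_libs = list(interface_libs) + list(stem_libs)
    kept = discovery.host_filter(
        condensed, host_mirnas, host_index, control_libs, parasite_libs,
        host_mirna_dist=cfg["host_mirna_dist"],
    )
    logger.info(
        "%s: %d sized, %d condensed, %d after host filter",
        isolate_id, len(sized), len(condensed), len(kept),
    )
    return discovery.call_hi_srnas(kept, interface_libs, stem_libs, cfg["fdr"], isolate_id)


def locus_channel(
    locus_summaries: Sequence[seq_io.LocusAlignmentSummary],
    predictions: Sequence[targeting.TargetInteraction],
    transcript_genes: Mapping[str, str],
    config: Mapping[str, object],
) -> tuple[list[confirmation.LocusCall], dict[str, confirmation.PhasingProfile]]:
    """Secondary-siRNA confirmation: locus-level NB differential accumulation
    (library ids LI* = interface, LC* = control stem) followed by the four
    locus filters; phasing profiles computed for confirmed loci."""
    cfg = seq_io.validate_config(dict(config))
    if not locus_summaries:
        return [], {}
    li_libs = sorted({s.library_id for s in locus_summaries if s.library_id.startswith("LI")})
    lc_libs = sorted({s.library_id for s in locus_summaries if s.library_id.startswith("LC")})
    genes = sorted({s.gene_id for s in locus_summaries})
    lib_order = li_libs + lc_libs
    count_matrix = np.zeros((len(genes), len(lib_order)))
    index = {(s.gene_id, s.library_id): len(s.reads) for s in locus_summaries}
    for gi, gene in enumerate(genes):
        for lj, lib in enumerate(lib_order):
            count_matrix[gi, lj] = index.get((gene, lib), 0)
    log2fc, pvals = discovery.nb_wald_test(
        count_matrix, list(range(len(li_libs))), list(range(len(li_libs), len(lib_order)))
    )
    padj = discovery.benjamini_hochberg(pvals)
    treatment_summaries = [s for s in locus_summaries if s.library_id.startswith("LI")]
    stats_by_gene = {}
    for gi, gene in enumerate(genes):
        stats_by_gene[gene] = confirmation.LocusStats.from_summaries(
            treatment_summaries,
            gene,
            up_regulated=bool(padj[gi] < cfg["fdr"] and log2fc[gi] > 0),
            padj=float(padj[gi]),
        )
    known_genes = set(transcript_genes.values())
    scoped = [p for p in predictions if transcript_genes.get(p.transcript_id) in known_genes]
    locus_calls = confirmation.secondary_sirna_confirm(
        stats_by_gene,
        scoped,
        transcript_genes,
        confirm_score=cfg["confirm_score"],
        unstranded_min=cfg["unstranded_min"],
        unstranded_max=cfg["unstranded_max"],
        min_depth=cfg["min_locus_depth"],
    )
    phasing: dict[str, confirmation.PhasingProfile] = {}
    for call in locus_calls:
        if call.confirmed and call.interaction is not None:
            positions = [
                r.pos5
                for s in treatment_summaries
                if s.gene_id == call.gene_id
                for r in s.reads
                if r.strand == "+"
            ]
            if positions:
                phasing[call.gene_id] = confirmation.phasing_profile(
                    positions, call.interaction.predicted_cut, cfg["phase_length"]
                )
    return locus_calls, phasing


def run_pipeline(
    srna_records: Sequence[seq_io.SequenceRecord],
    libraries: Mapping[str, Sequence[str]],
    host_mirnas: Sequence[seq_io.SequenceRecord],
    transcripts: Mapping[str, str],
    annotations: Mapping[str, seq_io.TranscriptAnnotation],
    degradome: Sequence[seq_io.DegradomeProfile],
    locus_summaries: Sequence[seq_io.LocusAlignmentSummary],
    homolog_sets: Sequence[covariation.HomologSet] = (),
    config: Mapping[str, object] | None = None,
) -> PipelineResult:
    """Run every stage in memory.

    ``libraries`` maps roles to library-id lists: per-isolate
    ``"<iso>_interface"`` / ``"<iso>_stem"`` plus shared ``"control"``.
    Locus summaries use library ids starting ``LI`` (interface) / ``LC``
    (control stem). Homolog set ``target_id``s name transcripts.
    """
    cfg = seq_io.validate_config(dict(config or {}))
    host_index = discovery.HostSequenceIndex(list(transcripts.values()))
    isolates = sorted(
        role[: -len("_interface")] for role in libraries if role.endswith("_interface")
    )
    if not isolates:
        raise PipelineError("discovery: no '<isolate>_interface' library role provided")

    hi: dict[str, list[discovery.HISRNA]] = {}
    for iso in isolates:
        stem_role = f"{iso}_stem"
        if stem_role not in libraries:
            raise PipelineError(f"discovery: isolate {iso!r} has no stem libraries")
        hi[iso] = discover_isolate(
            srna_records,
            libraries[f"{iso}_interface"],
            libraries[stem_role],
            libraries.get("control", []),
            host_mirnas,
            host_index,
            cfg,
            isolate_id=iso,
        )

    hi_pairs = [(iso, h.representative_seq) for iso, calls in hi.items() for h in calls]
    superfams = families.cluster_families(hi_pairs, max_dist=cfg["superfamily_dist"])
    strict = families.cluster_strict_families(hi_pairs, max_dist=cfg["family_dist"])

    unique_srnas = sorted({seq for _, seq in hi_pairs})
    predictions = targeting.scan_all(
        unique_srnas, dict(transcripts), cfg["confirm_score"], cfg["core_start"], cfg["core_end"]
    )

    # secondary-siRNA channel
    transcript_genes = {tid: ann.gene_id for tid, ann in annotations.items()}
    locus_calls, phasing = locus_channel(locus_summaries, predictions, transcript_genes, cfg)

    peak_calls: list[confirmation.PeakCall] = []
    if degradome:
        peak_calls = confirmation.degradome_confirm(
            degradome,
            predictions,
            annotations,
            confirm_score=cfg["confirm_score"],
            min_site_start=cfg["degradome_min_site_start"],
            fold_threshold=cfg["degradome_fold"],
            peak_window=cfg["peak_window"],
            require_control_fold=cfg["require_control_fold"],
        )

    result = PipelineResult(
        hi_srnas=hi,
        superfamilies=superfams,
        strict_families=strict,
        predictions=predictions,
        locus_calls=locus_calls,
        peak_calls=peak_calls,
        phasing=phasing,
    )
    result.confirmed_genes_locus = {c.gene_id for c in locus_calls if c.confirmed}
    result.confirmed_genes_degradome = {
        transcript_genes.get(c.transcript_id, c.transcript_id)
        for c in peak_calls
        if c.confirmed
    }
    result.confirmed_both = result.confirmed_genes_locus & result.confirmed_genes_degradome

    # covariation: pair each homolog set's transcript with the superfamily
    # contributing the most predictions onto it
    by_transcript: dict[str, set[str]] = {}
    for p in predictions:
        by_transcript.setdefault(p.transcript_id, set()).add(p.srna_seq)
    for hset in homolog_sets:
        srnas_here = by_transcript.get(hset.target_id, set())
        if not srnas_here:
            continue
        best, best_n = None, 0
        for fam in superfams:
            n = sum(1 for _, seq in fam.members if seq in srnas_here)
            if n > best_n:
                best, best_n = fam, n
        if best is None or best.size < 2:
            continue
        try:
            result.covariation_results[hset.target_id] = covariation.covariation_test(
                best.msa, hset
            )
            result.covariation_superfamily[hset.target_id] = best.id
        except ValueError as exc:
            logger.info("covariation skipped for %s: %s", hset.target_id, exc)
    return result


# ---------------------------------------------------------------------------
# File-level orchestration


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


STAGE_INPUTS = {
    "discovery": ["counts", "host_mirnas", "transcripts", "libraries"],
    "confirmation": ["annotations"],
}


def load_homolog_sets(
    homologs_path: str | Path, sites_path: str | Path
) -> list[covariation.HomologSet]:
    """Load homolog FASTA (ids ``species|target_id|frame_offset``) plus the
    per-target site-interval table."""
    records = seq_io.read_fasta(homologs_path)
    sites = pd.read_csv(sites_path, sep="\t").set_index("target_id")
    grouped: dict[str, dict[str, str]] = {}
    frames: dict[str, int] = {}
    for rec in records:
        species, target_id, frame = rec.id.split("|")
        grouped.setdefault(target_id, {})[species] = rec.seq
        frames[target_id] = int(frame)
    out = []
    for target_id, seqs in grouped.items():
        row = sites.loc[target_id]
        out.append(
            covariation.HomologSet(
                target_id=target_id,
                sequences=seqs,
                site_start=int(row["site_start"]),
                site_end=int(row["site_end"]),
                frame_offset=frames[target_id],
            )
        )
    return out


def run_all(
    inputs: Mapping[str, str],
    outdir: str | Path,
    config: Mapping[str, object] | None = None,
    resume: bool = False,
) -> PipelineResult:
    """File-level end-to-end run.

    ``inputs`` maps names (counts, host_mirnas, transcripts, annotations,
    degradome, locus_summaries, homologs, homolog_sites, libraries) to paths;
    outputs and a manifest land in ``outdir``. Every stage is deterministic
    given its inputs, so re-running over an existing output directory is
    idempotent; with ``resume=True`` a manifest matching the current input
    digests and config is logged as such before the (byte-identical) re-run.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = seq_io.validate_config(dict(config or {}))
    for stage, names in STAGE_INPUTS.items():
        for name in names:
            if name not in inputs or not Path(inputs[name]).exists():
                raise PipelineError(f"{stage}: missing input {name!r}")

    records = seq_io.read_count_table(inputs["counts"])
    host_mirnas = seq_io.read_fasta(inputs["host_mirnas"])
    transcripts = {r.id: r.seq for r in seq_io.read_fasta(inputs["transcripts"])}
    annotations = seq_io.read_annotations(inputs["annotations"], transcripts)
    with open(inputs["libraries"]) as fh:
        libraries = json.load(fh)
    degradome = (
        seq_io.read_degradome(inputs["degradome"]) if inputs.get("degradome") else []
    )
    locus_summaries = (
        seq_io.read_locus_summaries(inputs["locus_summaries"])
        if inputs.get("locus_summaries")
        else []
    )
    homolog_sets: list[covariation.HomologSet] = []
    if inputs.get("homologs") and inputs.get("homolog_sites"):
        homolog_sets = load_homolog_sets(inputs["homologs"], inputs["homolog_sites"])

    manifest_path = outdir / "manifest.json"
    input_digests = {
        name: _digest(Path(path)) for name, path in inputs.items() if Path(path).exists()
    }
    if resume and manifest_path.exists():
        previous = json.loads(manifest_path.read_text())
        if previous.get("inputs") == input_digests and previous.get("config") == _jsonable(cfg):
            logger.info("manifest matches inputs; reusing completed run in %s", outdir)

    result = run_pipeline(
        records, libraries, host_mirnas, transcripts, annotations,
        degradome, locus_summaries, homolog_sets, cfg,
    )
    outputs = write_result(result, outdir)
    manifest = {
        "config": _jsonable(cfg),
        "inputs": input_digests,
        "outputs": {name: _digest(Path(p)) for name, p in outputs.items()},
        "stages": ["discovery", "families", "targeting", "confirmation", "covariation"],
    }
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return result


def _jsonable(cfg: Mapping[str, object]) -> dict:
    return {k: (list(v) if isinstance(v, tuple) else v) for k, v in cfg.items()}


def write_result(result: PipelineResult, outdir: str | Path) -> dict[str, str]:
    """Write stage outputs as TSV tables; returns name -> path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    hi_rows = [
        {
            "isolate": iso,
            "representative_seq": h.representative_seq,
            "log2fc": h.log2fc,
            "padj": h.padj,
            "n_members": len(h.condensed.members),
            "total_count": h.condensed.total_count,
        }
        for iso, calls in result.hi_srnas.items()
        for h in calls
    ]
    paths["hi_srnas"] = str(outdir / "hi_srnas.tsv")
    pd.DataFrame(
        hi_rows,
        columns=["isolate", "representative_seq", "log2fc", "padj", "n_members", "total_count"],
    ).to_csv(paths["hi_srnas"], sep="\t", index=False)

    fam_rows = [
        {"id": fam.id, "size": fam.size, "isolate": iso, "seq": seq, "aligned": row}
        for fam in result.superfamilies
        for (iso, seq), row in zip(fam.members, fam.msa)
    ]
    paths["superfamilies"] = str(outdir / "superfamilies.tsv")
    pd.DataFrame(fam_rows, columns=["id", "size", "isolate", "seq", "aligned"]).to_csv(
        paths["superfamilies"], sep="\t", index=False
    )

    paths["predictions"] = str(outdir / "predictions.tsv")
    targeting.interactions_to_frame(result.predictions).to_csv(
        paths["predictions"], sep="\t", index=False
    )

    locus_rows = [
        {
            "gene_id": c.gene_id,
            "up_regulated": c.up_regulated,
            "pass_score": c.passes[0],
            "pass_unstranded": c.passes[1],
            "pass_size": c.passes[2],
            "pass_depth": c.passes[3],
            "confirmed": c.confirmed,
        }
        for c in result.locus_calls
    ]
    paths["locus_calls"] = str(outdir / "locus_calls.tsv")
    pd.DataFrame(
        locus_rows,
        columns=[
            "gene_id", "up_regulated", "pass_score", "pass_unstranded",
            "pass_size", "pass_depth", "confirmed",
        ],
    ).to_csv(paths["locus_calls"], sep="\t", index=False)

    peak_rows = [
        {
            "transcript_id": c.transcript_id,
            "srna_seq": c.srna_seq,
            "cut_1based": c.position + 1,
            "fold_vs_control": c.fold_vs_control,
            **{f"pass_{i + 1}": ok for i, ok in enumerate(c.passes)},
            "confirmed": c.confirmed,
        }
        for c in result.peak_calls
    ]
    paths["peak_calls"] = str(outdir / "peak_calls.tsv")
    pd.DataFrame(
        peak_rows,
        columns=["transcript_id", "srna_seq", "cut_1based", "fold_vs_control"]
        + [f"pass_{i + 1}" for i in range(6)]
        + ["confirmed"],
    ).to_csv(paths["peak_calls"], sep="\t", index=False)

    cov_rows = [
        {
            "target_id": target_id,
            "superfamily": result.covariation_superfamily.get(target_id, ""),
            "slope": res.slope,
            "pearson_r": res.pearson_r,
            "p_value": res.p_value,
            "n": res.n,
            "degenerate": res.degenerate,
        }
        for target_id, res in result.covariation_results.items()
    ]
    paths["covariation"] = str(outdir / "covariation.tsv")
    pd.DataFrame(
        cov_rows,
        columns=["target_id", "superfamily", "slope", "pearson_r", "p_value", "n", "degenerate"],
    ).to_csv(paths["covariation"], sep="\t", index=False)
    return paths
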