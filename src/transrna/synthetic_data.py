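"""Synthetic pipeline inputs with planted ground truth.

Every stage of the pipeline gets a generator that emulates the statistical
structure its real inputs would have, with a complete truth registry so that
recovery can be scored exactly:

* superfamilies whose members are reverse complements of species-level
  target-site variants (variation concentrated at synonymous codon
  positions, giving the three-nucleotide period), plus "null" families whose
  variation is decoupled from the homologs;
* host transcripts carrying planted target sites inside the CDS and a
  decoy class violating each confirmation filter exactly once;
* negative-binomially distributed sRNA libraries with interface
  up-regulation of planted sRNAs, host-derived reads, and low-abundance
  sequencing-error variant clouds;
* degradome 5'-end profiles with cleavage peaks at predicted cut sites, and
  21-nt-phased secondary-siRNA locus reads on both strands.

All generators are deterministic given a seed. Sequences derived from a
causative sRNA keep their mismatches to the host site in the sRNA 3' region
(outside the 5' core), so planted sites score ~2 — strong but imperfect
complementarity, as real confirmed sites show (a perfect complement would be
indistinguishable from a host-derived read and is removed by host
filtering).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .covariation import _CODON_TO_AA, HomologSet
from .discovery import levenshtein
from .seq_io import (
    DegradomeProfile,
    LocusAlignmentSummary,
    LocusRead,
    SequenceRecord,
    TranscriptAnnotation,
    reverse_complement,
)

NT = "ACGT"
ISOLATES = ("ccm", "cpe", "cgr", "cin")

_AA_TO_CODONS: dict[str, list[str]] = {}
for _codon, _aa in _CODON_TO_AA.items():
    _AA_TO_CODONS.setdefault(_aa, []).append(_codon)
_SENSE_AAS = sorted(aa for aa in _AA_TO_CODONS if aa != "*")


@dataclass
class ScenarioConfig:
    """Knobs of the default synthetic study.

    Rates emulate the structure the analysis assumes: high synonymous / low
    nonsynonymous divergence of target sites across host species, 8-fold
    interface induction of planted sRNAs, moderate NB overdispersion, and a
    small sequencing-error variant cloud around each abundant sRNA.
    """

    # superfamilies / homologs
    n_superfamilies: int = 6
    n_null_families: int = 2  # of the above, variation decoupled from homologs
    members_per_family: int = 8
    n_species: int = 12
    site_codons: int = 7  # 21-nt target sites
    flank_codons: int = 8
    synonymous_rate: float = 0.5  # per codon, per species
    nonsynonymous_rate: float = 0.02
    flank_sub_rate: float = 0.5  # per flank codon, any non-stop codon

    # sRNA libraries
    n_background_srnas: int = 60
    n_offsize_srnas: int = 10  # lengths outside 20-24, must be size-filtered
    n_host_srnas: int = 8  # exact host-transcript substrings
    n_host_mirnas: int = 5
    fold_change: float = 8.0
    base_mean: float = 100.0
    dispersion: float = 0.05
    n_interface: int = 3
    n_stem: int = 3
    n_control: int = 2
    error_variant_rate: float = 0.03  # of parent abundance
    n_error_variants: int = 2

    # transcriptome
    n_transcripts: int = 30
    transcript_len: int = 600
    cds_start: int = 51
    cds_len: int = 480

    # degradome / secondary siRNAs
    degradome_peak_depth: float = 50.0
    degradome_background: float = 0.02  # Poisson rate per position per replicate
    n_degradome_replicates: int = 3
    locus_depth: int = 120  # secondary-siRNA reads per interface library
    locus_fold: float = 8.0
    phasing_noise: float = 0.1
    srna_len: int = 21
    n_background_loci: int = 12  # non-differential sRNA loci (normalization anchor)
    background_locus_depth: float = 80.0

    def __post_init__(self) -> None:
        if not (self.synonymous_rate >= self.nonsynonymous_rate >= 0):
            raise ValueError("need synonymous_rate >= nonsynonymous_rate >= 0")
        if self.fold_change <= 1 or self.dispersion <= 0:
            raise ValueError("fold_change must be > 1 and dispersion > 0")
        if self.n_null_families > self.n_superfamilies:
            raise ValueError("n_null_families exceeds n_superfamilies")


@dataclass
class FamilyTruth:
    """Planted superfamily with its homologous target-site set."""

    family_id: str
    covarying: bool
    peptide: str
    base_site: str  # reference (host) site, in frame
    causative_site: str  # 2-synonymous-substitution variant, complement of the causative sRNA
    species_sites: dict[str, str]
    homologs: HomologSet
    members: list[tuple[str, str]]  # (isolate, srna_seq); member 0 = revcomp(base_site)

    @property
    def causative_srna(self) -> str:
        return reverse_complement(self.causative_site)


@dataclass
class PlantedSite:
    """One planted target site (true or decoy) in the host transcriptome."""

    kind: str  # "true" or a decoy class name
    channel: str  # "both", "degradome", "locus"
    family_id: str | None
    srna: str
    transcript_id: str
    gene_id: str
    site_start: int
    site_end: int
    cut_pos: int
    expected_fail_filter: int | None = None  # 1-based index in its channel's filter vector


@dataclass
class Scenario:
    """A complete synthetic study with its truth registry."""

    config: ScenarioConfig
    seed: int
    families: list[FamilyTruth]
    transcripts: dict[str, str]
    annotations: dict[str, TranscriptAnnotation]
    registry: list[PlantedSite]
    srna_records: list[SequenceRecord]
    host_mirnas: list[SequenceRecord]
    libraries: dict[str, list[str]]  # role -> library ids
    planted_hi: list[tuple[str, str]]  # (isolate, seq) expected discoverable
    host_filtered_hi: list[tuple[str, str]]  # planted but removed by host filtering
    expected_condensed_hi: list[tuple[str, str]]  # absorbed into a sibling cluster
    degradome: list[DegradomeProfile]
    locus_summaries: list[LocusAlignmentSummary]
    error_variants: dict[str, list[str]]  # parent seq -> variant seqs

    def truth_dict(self) -> dict:
        return {
            "seed": self.seed,
            "families": [
                {
                    "family_id": f.family_id,
                    "covarying": f.covarying,
                    "members": f.members,
                    "causative_srna": f.causative_srna,
                }
                for f in self.families
            ],
            "registry": [asdict(p) for p in self.registry],
            "planted_hi": self.planted_hi,
            "host_filtered_hi": self.host_filtered_hi,
            "expected_condensed_hi": self.expected_condensed_hi,
        }


# ---------------------------------------------------------------------------
# helpers


def _random_codon(rng: np.random.Generator, aa: str) -> str:
    options = _AA_TO_CODONS[aa]
    return options[int(rng.integers(len(options)))]


def _random_peptide(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(_SENSE_AAS), size=n))


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(NT), size=n))


def _evolve_site(
    rng: np.random.Generator, base_codons: list[str], syn_rate: float, nonsyn_rate: float
) -> str:
    out = []
    for codon in base_codons:
        u = rng.random()
        if u < syn_rate:
            out.append(_random_codon(rng, _CODON_TO_AA[codon]))
        elif u < syn_rate + nonsyn_rate:
            other = _SENSE_AAS[int(rng.integers(len(_SENSE_AAS)))]
            out.append(_random_codon(rng, other))
        else:
            out.append(codon)
    return "".join(out)


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def _causative_variant(rng: np.random.Generator, base_codons: list[str]) -> str:
    """Base site with >= 3 synonymous nucleotide substitutions, placed in the
    earliest codons possible (which pair with the sRNA 3' region, mostly
    outside the 5' core) so the variant's complement still scores well
    against the reference site yet sits outside the read-condensation radius."""
    codons = list(base_codons)
    diffs = 0
    for idx in range(len(codons)):
        if diffs >= 3:
            break
        aa = _CODON_TO_AA[codons[idx]]
        options = [c for c in _AA_TO_CODONS[aa] if c != codons[idx]]
        if not options:
            continue
        # prefer the synonymous codon adding the most substitutions
        best = max(options, key=lambda c: _hamming(c, codons[idx]))
        diffs += _hamming(best, codons[idx])
        codons[idx] = best
    return "".join(codons)


# ---------------------------------------------------------------------------
# generators


def make_superfamilies_and_homologs(
    cfg: ScenarioConfig, seed: int | np.random.Generator
) -> list[FamilyTruth]:
    """Plant superfamilies as complements of species-level target-site
    variants (covarying) or of an independent pseudo-site (null families)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    families = []
    for fam_idx in range(cfg.n_superfamilies):
        covarying = fam_idx >= cfg.n_null_families
        peptide = _random_peptide(rng, cfg.site_codons)
        base_codons = [_random_codon(rng, aa) for aa in peptide]
        base_site = "".join(base_codons)
        species = [f"sp{i + 1:02d}" for i in range(cfg.n_species)]
        sites = {species[0]: base_site}
        for sp in species[1:]:
            sites[sp] = _evolve_site(
                rng, base_codons, cfg.synonymous_rate, cfg.nonsynonymous_rate
            )
        causative_site = _causative_variant(rng, base_codons)
        sites[species[1]] = causative_site  # ensure the causative variant exists
        flank_left = [_random_codon(rng, aa) for aa in _random_peptide(rng, cfg.flank_codons)]
        flank_right = [_random_codon(rng, aa) for aa in _random_peptide(rng, cfg.flank_codons)]
        homolog_seqs = {}
        for sp in species:
            fl = [
                _random_codon(rng, _SENSE_AAS[int(rng.integers(len(_SENSE_AAS)))])
                if rng.random() < cfg.flank_sub_rate
                else c
                for c in flank_left
            ]
            fr = [
                _random_codon(rng, _SENSE_AAS[int(rng.integers(len(_SENSE_AAS)))])
                if rng.random() < cfg.flank_sub_rate
                else c
                for c in flank_right
            ]
            homolog_seqs[sp] = "".join(fl) + sites[sp] + "".join(fr)
        site_start = 3 * cfg.flank_codons
        homologs = HomologSet(
            target_id=f"PF_{fam_idx + 1}",
            sequences=homolog_seqs,
            site_start=site_start,
            site_end=site_start + 3 * cfg.site_codons,
        )
        # members: complements of sampled variants (covarying) or of an
        # independent pseudo-site's variants (null: same marginal process,
        # decoupled positions)
        pseudo_codons: list[str] | None = None
        null_perm: np.ndarray | None = None
        if not covarying:
            # an independent pseudo-site supplies the *positions* at which
            # null-family members vary; a fixed column permutation breaks the
            # codon-frame alignment so variation is decoupled from the
            # homologs' (frame-aligned, synonymous-site) pattern
            pseudo_pep = _random_peptide(rng, cfg.site_codons)
            pseudo_codons = [_random_codon(rng, aa) for aa in pseudo_pep]
            null_perm = rng.permutation(3 * cfg.site_codons)
        members: list[tuple[str, str]] = []
        for m in range(cfg.members_per_family):
            iso = ISOLATES[m % len(ISOLATES)]
            if m == 0:
                src = base_site
            elif m == 1:
                src = causative_site
            elif covarying:
                src = sites[species[int(rng.integers(1, len(species)))]]
            else:
                pseudo_base = "".join(pseudo_codons)
                variant = _evolve_site(
                    rng, pseudo_codons, cfg.synonymous_rate, cfg.nonsynonymous_rate
                )
                chars = list(causative_site)
                for i, (a, b) in enumerate(zip(pseudo_base, variant)):
                    if a != b:
                        j = int(null_perm[i])
                        options = [nt for nt in NT if nt != chars[j]]
                        chars[j] = options[int(rng.integers(3))]
                src = "".join(chars)
            members.append((iso, reverse_complement(src)))
        families.append(
            FamilyTruth(
                family_id=f"PFam_{fam_idx + 1}",
                covarying=covarying,
                peptide=peptide,
                base_site=base_site,
                causative_site=causative_site,
                species_sites=sites,
                homologs=homologs,
                members=members,
            )
        )
    return families


_DECOY_CLASSES = [
    # (kind, channel, expected_fail_filter within that channel's vector)
    ("near_tss", "degradome", 2),
    ("organellar", "degradome", 3),
    ("below_median", "degradome", 4),
    ("peak_2of3", "degradome", 5),
    ("low_fold", "degradome", 6),
    ("stranded", "locus", 2),
    ("wrong_size", "locus", 3),
    ("low_depth", "locus", 4),
    ("not_up", "locus", None),  # fails the up-regulation gate, not a vector slot
]


def make_host_transcriptome(
    cfg: ScenarioConfig,
    families: Sequence[FamilyTruth],
    seed: int | np.random.Generator,
) -> tuple[dict[str, str], dict[str, TranscriptAnnotation], list[PlantedSite]]:
    """Random CDS-bearing transcripts with planted true sites (one per
    family, inside the CDS, > 100 nt from the transcript start) and one decoy
    per confirmation filter."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_needed = len(families) + len(_DECOY_CLASSES)
    n_transcripts = max(cfg.n_transcripts, n_needed + 2)
    transcripts: dict[str, str] = {}
    annotations: dict[str, TranscriptAnnotation] = {}
    organellar_ids = set()
    for i in range(n_transcripts):
        tid = f"T{i + 1:03d}"
        transcripts[tid] = _random_seq(rng, cfg.transcript_len)
    registry: list[PlantedSite] = []
    tids = list(transcripts)
    site_len = 3 * cfg.site_codons

    def plant(tid: str, insert_pos: int, site: str) -> tuple[int, int]:
        seq = transcripts[tid]
        transcripts[tid] = seq[:insert_pos] + site + seq[insert_pos + len(site) :]
        return insert_pos, insert_pos + len(site)

    # true sites: full reference homolog region (flanks + site) at a codon
    # boundary deep inside the CDS
    for idx, fam in enumerate(families):
        tid = tids[idx]
        ref = fam.homologs.sequences[next(iter(fam.homologs.sequences))]
        insert = cfg.cds_start + 90  # codon boundary, site lands > 100 nt in
        plant(tid, insert, ref)
        site_start = insert + fam.homologs.site_start
        site_end = site_start + site_len
        registry.append(
            PlantedSite(
                kind="true",
                channel="both",
                family_id=fam.family_id,
                srna=fam.causative_srna,
                transcript_id=tid,
                gene_id=f"G{tid[1:]}",
                site_start=site_start,
                site_end=site_end,
                cut_pos=site_end - 10,
            )
        )
    # decoys: each its own transcript, its own causative sRNA (a 2-sub
    # synonymous variant complement, exactly like true sites)
    for d_idx, (kind, channel, fail_filter) in enumerate(_DECOY_CLASSES):
        tid = tids[len(families) + d_idx]
        pep = _random_peptide(rng, cfg.site_codons)
        codons = [_random_codon(rng, aa) for aa in pep]
        site = "".join(codons)
        srna = reverse_complement(_causative_variant(rng, codons))
        if kind == "near_tss":
            insert = 40  # site starts at/below the 100-nt TSS exclusion
        else:
            insert = cfg.cds_start + 120
        site_start, site_end = plant(tid, insert, site)
        if kind == "organellar":
            organellar_ids.add(tid)
        registry.append(
            PlantedSite(
                kind=kind,
                channel=channel,
                family_id=None,
                srna=srna,
                transcript_id=tid,
                gene_id=f"G{tid[1:]}",
                site_start=site_start,
                site_end=site_end,
                cut_pos=site_end - 10,
                expected_fail_filter=fail_filter,
            )
        )
    for tid, seq in transcripts.items():
        annotations[tid] = TranscriptAnnotation(
            transcript_id=tid,
            seq=seq,
            cds_start=cfg.cds_start,
            cds_end=cfg.cds_start + cfg.cds_len,
            organellar=tid in organellar_ids,
            gene_id=f"G{tid[1:]}",
        )
    return transcripts, annotations, registry


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float, size: int) -> np.ndarray:
    """Negative binomial with Var = mu + dispersion * mu^2."""
    if mean <= 0:
        return np.zeros(size, dtype=int)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


def _mutate(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    chars = list(seq)
    positions = rng.choice(len(chars), size=n_subs, replace=False)
    for pos in positions:
        options = [b for b in NT if b != chars[pos]]
        chars[pos] = options[int(rng.integers(3))]
    return "".join(chars)


def make_srna_libraries(
    cfg: ScenarioConfig,
    families: Sequence[FamilyTruth],
    registry: Sequence[PlantedSite],
    transcripts: dict[str, str],
    seed: int | np.random.Generator,
) -> tuple[
    list[SequenceRecord],
    list[SequenceRecord],
    dict[str, list[str]],
    list[tuple[str, str]],
    list[tuple[str, str]],
    dict[str, list[str]],
]:
    """NB-distributed sRNA count tables across per-isolate interface/stem
    libraries plus shared host-control libraries.

    Returns (records, host_mirnas, libraries, planted_hi, host_filtered_hi,
    error_variants). Planted sRNAs are 8-fold up in their isolate's interface
    libraries; member 0 of each covarying family is the perfect complement of
    the host site and is expected to be host-filtered.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    libraries: dict[str, list[str]] = {}
    for iso in ISOLATES:
        libraries[f"{iso}_interface"] = [f"{iso}_I{i + 1}" for i in range(cfg.n_interface)]
        libraries[f"{iso}_stem"] = [f"{iso}_S{i + 1}" for i in range(cfg.n_stem)]
    libraries["control"] = [f"C{i + 1}" for i in range(cfg.n_control)]
    all_libs = [lib for libs in libraries.values() for lib in libs]

    counts: dict[str, dict[str, int]] = {}

    def add(seq: str, lib_means: dict[str, float]) -> None:
        row = counts.setdefault(seq, {lib: 0 for lib in all_libs})
        for lib, mean in lib_means.items():
            row[lib] += int(_nb_draw(rng, mean, cfg.dispersion, 1)[0])

    planted_hi: list[tuple[str, str]] = []
    host_filtered: list[tuple[str, str]] = []
    expected_condensed: list[tuple[str, str]] = []
    error_variants: dict[str, list[str]] = {}

    # every family's reference site is planted in the host transcriptome, so
    # its perfect complement will be removed by host filtering (rule 2)
    host_site_seqs = {reverse_complement(fam.base_site) for fam in families}

    def plant_hi(iso: str, seq: str) -> None:
        means = {lib: cfg.base_mean * cfg.fold_change for lib in libraries[f"{iso}_interface"]}
        means.update({lib: cfg.base_mean for lib in libraries[f"{iso}_stem"]})
        add(seq, means)
        if seq in host_site_seqs:
            host_filtered.append((iso, seq))
        elif any(
            levenshtein(seq, prev) <= 2
            for p_iso, prev in planted_hi + host_filtered
            if p_iso == iso
        ):
            # within the condensation radius of an earlier same-isolate sRNA:
            # by design it will be absorbed into that cluster
            expected_condensed.append((iso, seq))
        else:
            planted_hi.append((iso, seq))
        variants = []
        for _ in range(cfg.n_error_variants):
            var = _mutate(rng, seq, int(rng.integers(1, 3)))
            if var in counts or var == seq:
                continue
            vmeans = {
                lib: mean * cfg.error_variant_rate for lib, mean in means.items()
            }
            add(var, vmeans)
            variants.append(var)
        error_variants[seq] = variants

    seen_members: set[tuple[str, str]] = set()
    for fam in families:
        for iso, seq in fam.members:
            if (iso, seq) in seen_members:
                continue
            seen_members.add((iso, seq))
            plant_hi(iso, seq)
    for site in registry:
        if site.kind != "true":
            plant_hi(ISOLATES[0], site.srna)

    # background parasite sRNAs: equal accumulation in interface and stem
    for _ in range(cfg.n_background_srnas):
        length = int(rng.integers(20, 25))
        seq = _random_seq(rng, length)
        means = {}
        for iso in ISOLATES:
            for lib in libraries[f"{iso}_interface"] + libraries[f"{iso}_stem"]:
                means[lib] = cfg.base_mean
        add(seq, means)
    # off-size reads, removed by the size filter
    for _ in range(cfg.n_offsize_srnas):
        length = int(rng.choice([18, 19, 25, 26]))
        seq = _random_seq(rng, length)
        add(seq, {lib: cfg.base_mean for lib in all_libs})
    # host-derived sRNAs: exact transcript substrings, present in control and
    # interface (host tissue) but not parasite stems
    tids = list(transcripts)
    for _ in range(cfg.n_host_srnas):
        tid = tids[int(rng.integers(len(tids)))]
        start = int(rng.integers(0, len(transcripts[tid]) - cfg.srna_len))
        seq = transcripts[tid][start : start + cfg.srna_len]
        means = {lib: cfg.base_mean for lib in libraries["control"]}
        for iso in ISOLATES:
            for lib in libraries[f"{iso}_interface"]:
                means[lib] = cfg.base_mean
        add(seq, means)
    # host miRNAs: annotated set; one also sequenced in parasite libraries
    host_mirnas = [
        SequenceRecord(id=f"miR{i + 1}", seq=_random_seq(rng, cfg.srna_len))
        for i in range(cfg.n_host_mirnas)
    ]
    if host_mirnas:
        add(
            host_mirnas[0].seq,
            {lib: cfg.base_mean for lib in libraries["control"] + libraries["ccm_interface"]},
        )
    records = [
        SequenceRecord(id=seq, seq=seq, counts=row) for seq, row in counts.items()
    ]
    return (
        records, host_mirnas, libraries, planted_hi, host_filtered,
        expected_condensed, error_variants,
    )


def make_degradome_and_phasing(
    cfg: ScenarioConfig,
    registry: Sequence[PlantedSite],
    annotations: dict[str, TranscriptAnnotation],
    seed: int | np.random.Generator,
) -> tuple[list[DegradomeProfile], list[LocusAlignmentSummary]]:
    """Degradome profiles (treatment + control replicates) and phased
    secondary-siRNA locus read tables, with one decoy violating each filter."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_reps = cfg.n_degradome_replicates
    treatment_reps = [f"HD{i + 1}" for i in range(n_reps)]
    control_reps = [f"CD{i + 1}" for i in range(n_reps)]
    by_transcript = {p.transcript_id: p for p in registry}
    profiles: list[DegradomeProfile] = []
    for tid, ann in annotations.items():
        planted = by_transcript.get(tid)
        bg_rate = cfg.degradome_background
        if planted is not None and planted.kind == "below_median":
            bg_rate = 10.0  # heavily occupied gene so the peak sits below median
        for rep_idx, rep in enumerate(treatment_reps):
            depth_arr = rng.poisson(bg_rate, size=len(ann.seq))
            prof = DegradomeProfile(tid, rep, "treatment")
            prof.depth = {int(i): int(c) for i, c in enumerate(depth_arr) if c > 0}
            if planted is not None and planted.channel in ("both", "degradome"):
                cut = planted.cut_pos
                if planted.kind == "below_median":
                    prof.depth[cut] = 5  # >= 10-fold over empty control, below median
                elif planted.kind == "peak_2of3" and rep_idx == n_reps - 1:
                    prof.depth.pop(cut, None)  # absent from the last replicate
                else:
                    prof.depth[cut] = int(
                        max(1, rng.poisson(cfg.degradome_peak_depth))
                    )
            profiles.append(prof)
        for rep in control_reps:
            depth_arr = rng.poisson(cfg.degradome_background, size=len(ann.seq))
            prof = DegradomeProfile(tid, rep, "control")
            prof.depth = {int(i): int(c) for i, c in enumerate(depth_arr) if c > 0}
            if planted is not None and planted.kind == "low_fold":
                # control carries a fifth of the treatment peak: fold 5 < 10
                prof.depth[planted.cut_pos] = int(round(cfg.degradome_peak_depth / 5))
            else:
                prof.depth.pop(planted.cut_pos, None) if planted else None
            profiles.append(prof)

    interface_libs = [f"LI{i + 1}" for i in range(3)]
    control_libs = [f"LC{i + 1}" for i in range(3)]
    summaries: list[LocusAlignmentSummary] = []

    def phased_reads(
        planted: PlantedSite, n: int, strands: Sequence[str], lengths: Sequence[int]
    ) -> list[LocusRead]:
        reads = []
        ann = annotations[planted.transcript_id]
        max_pos = len(ann.seq) - 26
        for _ in range(n):
            k = int(rng.integers(0, 9))
            if rng.random() < cfg.phasing_noise:
                pos = int(rng.integers(planted.cut_pos, min(planted.cut_pos + 190, max_pos)))
            else:
                pos = planted.cut_pos + 21 * k
            strand = strands[int(rng.integers(len(strands)))]
            if strand == "-":
                pos += 2  # duplex 2-nt 3' overhang
            length = int(lengths[int(rng.integers(len(lengths)))])
            reads.append(LocusRead(pos5=min(pos, max_pos), length=length, strand=strand))
        return reads

    for planted in registry:
        if planted.channel not in ("both", "locus"):
            continue
        strands = ("+", "-")
        lengths: Sequence[int] = (21, 21, 22)
        per_lib = cfg.locus_depth
        control_mean = cfg.locus_depth / cfg.locus_fold
        if planted.kind == "stranded":
            strands = ("+",)
        elif planted.kind == "wrong_size":
            lengths = (24,)
        elif planted.kind == "low_depth":
            pass  # handled below: 19 reads total across interface libraries
        elif planted.kind == "not_up":
            control_mean = cfg.locus_depth
        if planted.kind == "low_depth":
            totals = [7, 6, 6]
            for lib, n in zip(interface_libs, totals):
                summary = LocusAlignmentSummary(planted.gene_id, lib)
                summary.reads = phased_reads(planted, n, strands, lengths)
                summaries.append(summary)
            for lib in control_libs:
                summaries.append(LocusAlignmentSummary(planted.gene_id, lib))
            continue
        for lib in interface_libs:
            n = int(rng.poisson(per_lib))
            summary = LocusAlignmentSummary(planted.gene_id, lib)
            summary.reads = phased_reads(planted, max(n, 21), strands, lengths)
            summaries.append(summary)
        for lib in control_libs:
            n = int(rng.poisson(control_mean))
            summary = LocusAlignmentSummary(planted.gene_id, lib)
            summary.reads = phased_reads(planted, n, strands, lengths)
            summaries.append(summary)

    # non-differential background loci (ordinary sRNA-producing genes):
    # unphased reads of mixed sizes, equal accumulation in both conditions —
    # the normalization anchor a genome-wide locus table would provide
    planted_tids = {p.transcript_id for p in registry}
    free_tids = [tid for tid in annotations if tid not in planted_tids]
    for tid in free_tids[: cfg.n_background_loci]:
        ann = annotations[tid]
        gene = ann.gene_id
        for lib in interface_libs + control_libs:
            n = int(rng.poisson(cfg.background_locus_depth))
            summary = LocusAlignmentSummary(gene, lib)
            for _ in range(n):
                pos = int(rng.integers(0, len(ann.seq) - 26))
                summary.reads.append(
                    LocusRead(
                        pos5=pos,
                        length=int(rng.integers(20, 25)),
                        strand="+-"[int(rng.integers(2))],
                    )
                )
            summaries.append(summary)
    return profiles, summaries


def make_scenario(cfg: ScenarioConfig | None = None, seed: int = 0) -> Scenario:
    """Generate the complete default study with its truth registry."""
    cfg = cfg or ScenarioConfig()
    rng = np.random.default_rng(seed)
    families = make_superfamilies_and_homologs(cfg, rng)
    transcripts, annotations, registry = make_host_transcriptome(cfg, families, rng)
    (
        records, host_mirnas, libraries, planted_hi, host_filtered,
        expected_condensed, error_variants,
    ) = make_srna_libraries(cfg, families, registry, transcripts, rng)
    # anchor each family's homolog set to its planted target transcript
    for fam in families:
        target = next((p for p in registry if p.family_id == fam.family_id), None)
        if target is not None:
            fam.homologs.target_id = target.transcript_id
    degradome, locus_summaries = make_degradome_and_phasing(cfg, registry, annotations, rng)
    return Scenario(
        config=cfg,
        seed=seed,
        families=families,
        transcripts=transcripts,
        annotations=annotations,
        registry=registry,
        srna_records=records,
        host_mirnas=host_mirnas,
        libraries=libraries,
        planted_hi=planted_hi,
        host_filtered_hi=host_filtered,
        expected_condensed_hi=expected_condensed,
        degradome=degradome,
        locus_summaries=locus_summaries,
        error_variants=error_variants,
    )


def write_scenario(scenario: Scenario, outdir: str) -> dict[str, str]:
    """Emit every file format the pipeline reads, plus truth.json."""
    import json
    from pathlib import Path

    from . import seq_io

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": str(out / "srna_counts.tsv"),
        "host_mirnas": str(out / "host_mirnas.fa"),
        "transcripts": str(out / "host_transcripts.fa"),
        "annotations": str(out / "annotations.tsv"),
        "degradome": str(out / "degradome.tsv"),
        "locus_summaries": str(out / "locus_reads.tsv"),
        "homologs": str(out / "homologs.fa"),
        "homolog_sites": str(out / "homolog_sites.tsv"),
        "libraries": str(out / "libraries.json"),
        "truth": str(out / "truth.json"),
    }
    seq_io.write_count_table(scenario.srna_records, paths["counts"])
    seq_io.write_fasta(scenario.host_mirnas, paths["host_mirnas"])
    seq_io.write_fasta(
        [seq_io.SequenceRecord(id=tid, seq=seq) for tid, seq in scenario.transcripts.items()],
        paths["transcripts"],
    )
    seq_io.write_annotations(scenario.annotations.values(), paths["annotations"])
    seq_io.write_degradome(scenario.degradome, paths["degradome"])
    seq_io.write_locus_summaries(scenario.locus_summaries, paths["locus_summaries"])
    homolog_records = []
    site_rows = []
    for fam in scenario.families:
        target_tid = fam.homologs.target_id
        for sp, seq in fam.homologs.sequences.items():
            homolog_records.append(
                seq_io.SequenceRecord(id=f"{sp}|{target_tid}|0", seq=seq)
            )
        site_rows.append(
            {
                "target_id": target_tid,
                "site_start": fam.homologs.site_start,
                "site_end": fam.homologs.site_end,
            }
        )
    seq_io.write_fasta(homolog_records, paths["homologs"])
    import pandas as pd

    pd.DataFrame(site_rows).to_csv(paths["homolog_sites"], sep="\t", index=False)
    with open(paths["libraries"], "w") as fh:
        json.dump(scenario.libraries, fh, indent=1)
    with open(paths["truth"], "w") as fh:
        json.dump(scenario.truth_dict(), fh, indent=1)
    return paths
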