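"""Multi-stage prioritization of putative genomic driver mutations.

Per-tumor SNV catalogs (VarScan-style calls, already annotated with gene,
protein change and VAF) are reduced to putative driver mutations through a
ladder of filters that encode one idea: a driver is a *truncal* mutation — a
clonal, high-VAF somatic event — in a gene recurrently mutated in human
cancer, at a position mutated in human tumors.

Stages, in order:

1. call floor: VAF < 5% calls are discarded;
2. germline/artifact removal: SNVs that look like strain SNPs (known-SNP
   list, shared across a genotype group, clustered in one sample, VAF 100%,
   or present in more than ``snp_max_samples`` samples) are flagged;
3. a *cancer-gene branch*: non-synonymous SNVs in a curated cancer-gene
   list with VAF above the clonality floor;
4. an *all-gene branch*: non-synonymous SNVs in any gene, inside the
   mean +/- 3 SD VAF band of the cohort's known driver mutations, in genes
   whose human homolog carries a recurrent mutation (>= 5 patients), with
   VAF consistent with the tumor's reference driver, at amino-acid positions
   mutated in human cancer;
5. finalization: both branches are merged, candidates below 65% of the
   tumor's reference VAF are dropped, and candidates whose identical
   amino-acid change is seen in more than ten human patients are promoted to
   *initiating* drivers.

Every SNV carries an auditable ``filter_trail`` of (stage, passed, reason)
tuples recording how far it got and why it stopped.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .spectrum import classify_substitution

logger = logging.getLogger("mutopt")

EFFECTS = ("synonymous", "missense", "nonsense", "other")
NONSYNONYMOUS_EFFECTS = ("missense", "nonsense")

TIER_ORDER = ("rejected", "cancer_gene_hit", "putative_driver", "initiating_driver")


@dataclass(frozen=True)
class SNVRecord:
    """One somatic single-nucleotide variant call in one tumor."""

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    tri_context: str
    gene: str
    effect: str
    aa_change: str
    vaf: float
    group_label: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"VAF {self.vaf} outside [0, 1]")
        if self.effect not in EFFECTS:
            raise ValueError(f"effect {self.effect!r} not in {EFFECTS}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def substitution_class(self) -> str:
        return classify_substitution(self.tri_context, self.alt).label


_AA_RE = re.compile(r"^([A-Z\*])(\d+)([A-Z\*])$")


def aa_position(aa_change: str) -> Optional[int]:
    """Extract the residue number from a protein change like 'Q61L'."""
    m = _AA_RE.match(aa_change.strip()) if aa_change else None
    return int(m.group(2)) if m else None


@dataclass(frozen=True)
class RecurrenceEntry:
    """One human-recurrence record: a mutation seen in ``patient_count`` patients."""

    gene: str
    human_gene: str
    aa_position: int
    aa_change: str
    patient_count: int

    def __post_init__(self) -> None:
        if self.patient_count < 0:
            raise ValueError("patient_count must be >= 0")


class RecurrenceCatalog:
    """Lookup structure over human-recurrence entries, keyed by mouse gene.

    Stands in for interactive ICGC queries: per (gene, position, change) the
    number of human cancer patients carrying the homologous mutation.
    """

    def __init__(self, entries: Iterable[RecurrenceEntry]):
        self.entries = list(entries)
        self._by_gene: dict[str, list[RecurrenceEntry]] = {}
        for e in self.entries:
            self._by_gene.setdefault(e.gene.upper(), []).append(e)

    def __len__(self) -> int:
        return len(self.entries)

    def gene_max_count(self, gene: str) -> int:
        return max(
            (e.patient_count for e in self._by_gene.get(gene.upper(), [])), default=0
        )

    def position_known(self, gene: str, position: Optional[int]) -> bool:
        if position is None:
            return False
        return any(
            e.aa_position == position for e in self._by_gene.get(gene.upper(), [])
        )

    def change_count(self, gene: str, aa_change: str) -> int:
        return max(
            (
                e.patient_count
                for e in self._by_gene.get(gene.upper(), [])
                if e.aa_change == aa_change
            ),
            default=0,
        )


@dataclass
class FilterConfig:
    """All numeric thresholds of the ladder, with the published defaults."""

    min_vaf_call: float = 0.05
    snp_group_min_shared: int = 2
    snp_cluster_window_bp: int = 100
    snp_max_samples: int = 8
    vaf_band: Optional[tuple[float, float]] = None  # None: derive from drivers
    rel_band: tuple[float, float] = (0.5, 1.5)
    rel_floor: float = 0.65
    gene_recurrence_min: int = 5
    initiating_recurrence_min: int = 11  # "more than ten"
    reference_genes: tuple[str, ...] = ("KRAS", "BRAF")

    def __post_init__(self) -> None:
        if self.vaf_band is not None and not self.vaf_band[0] < self.vaf_band[1]:
            raise ValueError("vaf_band low must be < high")

    def is_reference_gene(self, gene: str) -> bool:
        return gene.upper() in {g.upper() for g in self.reference_genes}


TrailEntry = tuple[str, bool, str]


@dataclass
class DriverCandidate:
    """An SNV with its substitution class, filter trail and final tier."""

    snv: SNVRecord
    substitution_class: str = ""
    trail: list[TrailEntry] = field(default_factory=list)
    tier: str = "rejected"

    def __post_init__(self) -> None:
        if not self.substitution_class:
            self.substitution_class = self.snv.substitution_class

    def log(self, stage: str, passed: bool, reason: str = "") -> bool:
        self.trail.append((stage, passed, reason))
        return passed

    @property
    def passed_all(self) -> bool:
        return all(ok for _, ok, _ in self.trail)


def vaf_thresholds(driver_vafs: Sequence[float]) -> tuple[float, float]:
    """Clonality band (mean - 3 SD, mean + 3 SD) of reference-driver VAFs.

    Uses the sample (n-1) standard deviation; the band is clipped to [0, 1].
    """
    vafs = np.asarray(list(driver_vafs), dtype=float)
    if vafs.size < 2:
        raise ValueError("need at least 2 driver VAFs to estimate a band")
    if vafs.max() == vafs.min():
        warnings.warn("driver VAFs are identical; degenerate VAF band")
        return (float(vafs[0]), float(vafs[0]))
    mean = float(vafs.mean())
    sd = float(vafs.std(ddof=1))
    low = max(0.0, mean - 3.0 * sd)
    high = min(1.0, mean + 3.0 * sd)
    return (low, high)


def remove_snps(
    snvs: Sequence[SNVRecord],
    config: FilterConfig,
    known_snps: Optional[set[tuple[str, int]]] = None,
) -> tuple[list[SNVRecord], list[tuple[SNVRecord, str]]]:
    """Flag probable germline SNPs / artifacts in the pooled cohort.

    Rules (any one flags the SNV): position on the known-SNP list; identical
    SNV in >= ``snp_group_min_shared`` samples of the same genotype group;
    >= 2 SNVs within ``snp_cluster_window_bp`` of each other in one sample;
    VAF exactly 100%; identical SNV in more than ``snp_max_samples`` samples.
    Returns (kept, flagged-with-reason).
    """
    known = known_snps or set()
    by_key_samples: dict[tuple, set[str]] = {}
    by_key_group: dict[tuple, dict[str, set[str]]] = {}
    for s in snvs:
        by_key_samples.setdefault(s.key, set()).add(s.sample_id)
        by_key_group.setdefault(s.key, {}).setdefault(s.group_label, set()).add(
            s.sample_id
        )

    clustered: set[int] = set()  # indices flagged by the coordinate-cluster rule
    by_sample_chrom: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for i, s in enumerate(snvs):
        by_sample_chrom.setdefault((s.sample_id, s.chrom), []).append((s.pos, i))
    for positions in by_sample_chrom.values():
        positions.sort()
        for (p1, i1), (p2, i2) in zip(positions, positions[1:]):
            if p2 - p1 <= config.snp_cluster_window_bp:
                clustered.add(i1)
                clustered.add(i2)

    kept: list[SNVRecord] = []
    flagged: list[tuple[SNVRecord, str]] = []
    for i, s in enumerate(snvs):
        reason = ""
        if (s.chrom, s.pos) in known:
            reason = "known SNP position"
        elif any(
            len(samples) >= config.snp_group_min_shared
            for samples in by_key_group[s.key].values()
        ):
            reason = "shared within genotype group"
        elif i in clustered:
            reason = "clustered by genomic coordinates"
        elif s.vaf == 1.0:
            reason = "VAF 100%"
        elif len(by_key_samples[s.key]) > config.snp_max_samples:
            reason = f"present in > {config.snp_max_samples} samples"
        if reason:
            flagged.append((s, reason))
        else:
            kept.append(s)
    return kept, flagged


def reference_driver_vafs(
    snvs: Sequence[SNVRecord], config: FilterConfig
) -> dict[str, float]:
    """Per sample, the VAF of its known (reference-gene) driver mutation.

    A sample is reference-mutant if it carries a non-synonymous SNV in one of
    ``config.reference_genes`` (Kras/Braf by default); the highest such VAF
    is the reference. Samples without one are absent from the mapping.
    """
    out: dict[str, float] = {}
    for s in snvs:
        if s.effect in NONSYNONYMOUS_EFFECTS and config.is_reference_gene(s.gene):
            out[s.sample_id] = max(out.get(s.sample_id, 0.0), s.vaf)
    return out


def cancer_gene_branch(
    snvs: Sequence[SNVRecord],
    gene_list: Iterable[str],
    low: float,
    config: Optional[FilterConfig] = None,
) -> list[DriverCandidate]:
    """Prioritize non-synonymous SNVs in curated cancer genes above the VAF floor.

    Keeps SNVs in listed genes that are non-synonymous, with VAF strictly
    above ``low`` (the mean - 3 SD clonality floor) and below 100%. Returns a
    candidate per input SNV; survivors get tier ``cancer_gene_hit``.
    """
    genes = {g.strip().upper() for g in gene_list if g and g.strip()}
    if not genes:
        raise ValueError("empty cancer gene list")
    out = []
    for s in snvs:
        c = DriverCandidate(s)
        ok = c.log(
            "cancer_gene:listed_gene",
            s.gene.upper() in genes,
            f"{s.gene} not in cancer gene list",
        )
        if ok:
            ok = c.log(
                "cancer_gene:non_synonymous",
                s.effect in NONSYNONYMOUS_EFFECTS,
                f"effect {s.effect}",
            )
        if ok:
            ok = c.log(
                "cancer_gene:vaf_floor", s.vaf > low, f"VAF {s.vaf:.3f} below VAF floor"
            )
        if ok:
            ok = c.log("cancer_gene:not_full_vaf", s.vaf < 1.0, "VAF 100%")
        c.tier = "cancer_gene_hit" if ok else "rejected"
        out.append(c)
    return out


def all_gene_branch(
    snvs: Sequence[SNVRecord],
    recurrence: RecurrenceCatalog,
    band: tuple[float, float],
    ref_driver_vaf: Mapping[str, float],
    config: FilterConfig,
) -> list[DriverCandidate]:
    """Expand the driver search to all genes via seven ordered filters.

    (1) non-synonymous effect; (2) VAF inside the clonality ``band``;
    (3) single SNV per gene per sample; (4) human homolog recurrently
    mutated (>= ``gene_recurrence_min`` patients); (5) VAF inside
    ``rel_band`` x the tumor's reference-driver VAF (skipped for tumors
    without one); (6) not present in more than ``snp_max_samples`` samples;
    (7) amino-acid position mutated in human, or identical amino-acid
    change catalogued. Stages 4 and 7 are disabled when
    ``gene_recurrence_min`` is 0 (degenerate configuration).
    """
    if recurrence is None:
        raise ValueError("recurrence catalog is required")
    gene_sample_counts: dict[tuple[str, str], int] = {}
    key_samples: dict[tuple, set[str]] = {}
    for s in snvs:
        gene_sample_counts[(s.sample_id, s.gene.upper())] = (
            gene_sample_counts.get((s.sample_id, s.gene.upper()), 0) + 1
        )
        key_samples.setdefault(s.key, set()).add(s.sample_id)

    low, high = band
    out = []
    for s in snvs:
        c = DriverCandidate(s)
        ok = c.log(
            "all_gene:non_synonymous",
            s.effect in NONSYNONYMOUS_EFFECTS,
            f"effect {s.effect}",
        )
        if ok:
            ok = c.log(
                "all_gene:vaf_band",
                low <= s.vaf <= high,
                f"VAF {s.vaf:.3f} outside ({low:.3f}, {high:.3f})",
            )
        if ok:
            ok = c.log(
                "all_gene:single_snv_per_gene",
                gene_sample_counts[(s.sample_id, s.gene.upper())] < 2,
                "multiple SNVs in gene in this sample",
            )
        if ok and config.gene_recurrence_min > 0:
            ok = c.log(
                "all_gene:gene_recurrence",
                recurrence.gene_max_count(s.gene) >= config.gene_recurrence_min,
                f"human homolog below {config.gene_recurrence_min} patients",
            )
        if ok and s.sample_id in ref_driver_vaf:
            ref = ref_driver_vaf[s.sample_id]
            lo, hi = config.rel_band[0] * ref, config.rel_band[1] * ref
            ok = c.log(
                "all_gene:relative_vaf_band",
                lo <= s.vaf <= hi,
                f"VAF {s.vaf:.3f} outside ({lo:.3f}, {hi:.3f}) of reference",
            )
        if ok:
            ok = c.log(
                "all_gene:max_samples",
                len(key_samples[s.key]) <= config.snp_max_samples,
                f"present in > {config.snp_max_samples} samples",
            )
        if ok and config.gene_recurrence_min > 0:
            pos = aa_position(s.aa_change)
            conserved = recurrence.position_known(s.gene, pos) or (
                recurrence.change_count(s.gene, s.aa_change) > 0
            )
            ok = c.log(
                "all_gene:human_position",
                conserved,
                "position not mutated in human cancer",
            )
        c.tier = "putative_driver" if ok else "rejected"
        out.append(c)
    return out


def _tier_rank(tier: str) -> int:
    return TIER_ORDER.index(tier)


def finalize_drivers(
    candidates: Sequence[DriverCandidate],
    ref_driver_vaf: Mapping[str, float],
    recurrence: RecurrenceCatalog,
    config: FilterConfig,
) -> list[DriverCandidate]:
    """Merge branch survivors, apply the relative-VAF floor, assign tiers.

    Cancer-gene-branch survivors join the final list only if their amino-acid
    position is mutated in human patients (unless recurrence filtering is
    disabled). The per-tumor reference VAF is the known Kras/Braf driver VAF
    where present, otherwise the tumor's highest surviving candidate VAF;
    candidates below ``rel_floor`` x reference are dropped. Candidates whose
    identical amino-acid change is catalogued in >=
    ``initiating_recurrence_min`` human patients become initiating drivers.
    """
    survivors: dict[tuple[str, str, int, str], DriverCandidate] = {}
    for c in candidates:
        if c.tier == "rejected":
            continue
        c = DriverCandidate(c.snv, c.substitution_class, list(c.trail), c.tier)
        if c.tier == "cancer_gene_hit" and config.gene_recurrence_min > 0:
            pos = aa_position(c.snv.aa_change)
            known = recurrence.position_known(c.snv.gene, pos)
            if not c.log(
                "finalize:human_position", known, "position not mutated in human"
            ):
                c.tier = "rejected"
                continue
        key = (c.snv.sample_id, c.snv.chrom, c.snv.pos, c.snv.alt)
        prev = survivors.get(key)
        if prev is None:
            survivors[key] = c
        else:  # union of both branches: merge trails, highest tier wins
            prev.trail.extend(c.trail)
            if _tier_rank(c.tier) > _tier_rank(prev.tier):
                prev.tier = c.tier

    by_sample: dict[str, list[DriverCandidate]] = {}
    for c in survivors.values():
        by_sample.setdefault(c.snv.sample_id, []).append(c)

    final: list[DriverCandidate] = []
    for sample, cands in by_sample.items():
        ref = ref_driver_vaf.get(sample)
        if ref is None:
            ref = max(c.snv.vaf for c in cands)
        for c in cands:
            ok = c.log(
                "finalize:relative_vaf_floor",
                c.snv.vaf >= config.rel_floor * ref,
                f"VAF {c.snv.vaf:.3f} < {config.rel_floor:.2f} x reference {ref:.3f}",
            )
            if not ok:
                c.tier = "rejected"
                continue
            n_patients = recurrence.change_count(c.snv.gene, c.snv.aa_change)
            if n_patients >= config.initiating_recurrence_min:
                c.log(
                    "finalize:initiating",
                    True,
                    f"identical change in {n_patients} patients",
                )
                c.tier = "initiating_driver"
            final.append(c)
    final.sort(key=lambda c: (c.snv.sample_id, c.snv.chrom, c.snv.pos, c.snv.alt))
    return final


@dataclass
class LadderResult:
    """Full output of the prioritization ladder, auditable end to end."""

    final: list[DriverCandidate]
    all_candidates: list[DriverCandidate]  # one per input SNV, with trail + tier
    vaf_band: tuple[float, float]
    ref_driver_vaf: dict[str, float]
    flagged_snps: list[tuple[SNVRecord, str]]

    def drivers_by_sample(self) -> dict[str, list[DriverCandidate]]:
        out: dict[str, list[DriverCandidate]] = {}
        for c in self.final:
            out.setdefault(c.snv.sample_id, []).append(c)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.final:
            s = c.snv
            rows.append(
                {
                    "sample_id": s.sample_id,
                    "chrom": s.chrom,
                    "pos": s.pos,
                    "ref": s.ref,
                    "alt": s.alt,
                    "gene": s.gene,
                    "aa_change": s.aa_change,
                    "vaf": s.vaf,
                    "substitution_class": c.substitution_class,
                    "tier": c.tier,
                }
            )
        cols = [
            "sample_id", "chrom", "pos", "ref", "alt", "gene",
            "aa_change", "vaf", "substitution_class", "tier",
        ]
        return pd.DataFrame(rows, columns=cols)


def run_driver_ladder(
    snvs: Sequence[SNVRecord],
    gene_list: Iterable[str],
    recurrence: RecurrenceCatalog,
    config: Optional[FilterConfig] = None,
    known_snps: Optional[set[tuple[str, int]]] = None,
) -> LadderResult:
    """Run the complete ladder: call floor, SNP removal, both branches, finalize."""
    config = config or FilterConfig()

    called: list[SNVRecord] = []
    precalls: dict[int, DriverCandidate] = {}
    for i, s in enumerate(snvs):
        if s.vaf < config.min_vaf_call:
            c = DriverCandidate(s)
            c.log("call:min_vaf", False, f"VAF {s.vaf:.3f} < {config.min_vaf_call}")
            precalls[i] = c
        else:
            called.append(s)

    kept, flagged = remove_snps(called, config, known_snps)
    snp_rejects = []
    for s, reason in flagged:
        c = DriverCandidate(s)
        c.log("snp_filter", False, reason)
        snp_rejects.append(c)

    ref_vafs = reference_driver_vafs(kept, config)
    if config.vaf_band is not None:
        band = config.vaf_band
    else:
        driver_vafs = [
            s.vaf
            for s in kept
            if s.effect in NONSYNONYMOUS_EFFECTS and config.is_reference_gene(s.gene)
        ]
        band = vaf_thresholds(driver_vafs)
        logger.info(
            "clonality VAF band from %d reference-driver VAFs: (%.3f, %.3f)",
            len(driver_vafs), band[0], band[1],
        )

    cg = cancer_gene_branch(kept, gene_list, band[0], config)
    ag = all_gene_branch(kept, recurrence, band, ref_vafs, config)
    final = finalize_drivers(cg + ag, ref_vafs, recurrence, config)

    final_keys = {(c.snv.sample_id, *c.snv.key) for c in final}
    merged: list[DriverCandidate] = []
    per_snv: dict[tuple, DriverCandidate] = {}
    for c in cg + ag:
        k = (c.snv.sample_id, *c.snv.key)
        prev = per_snv.get(k)
        if prev is None:
            per_snv[k] = DriverCandidate(c.snv, c.substitution_class, list(c.trail), c.tier)
        else:
            prev.trail.extend(c.trail)
            if _tier_rank(c.tier) > _tier_rank(prev.tier):
                prev.tier = c.tier
    for fc in final:
        per_snv[(fc.snv.sample_id, *fc.snv.key)] = fc
    for k, c in per_snv.items():
        if k not in final_keys and c.tier != "rejected":
            c.log("finalize:dropped", False, "removed during finalization")
            c.tier = "rejected"
        merged.append(c)
    merged.extend(snp_rejects)
    merged.extend(precalls.values())

    return LadderResult(
        final=final,
        all_candidates=merged,
        vaf_band=band,
        ref_driver_vaf=ref_vafs,
        flagged_snps=flagged,
    )
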