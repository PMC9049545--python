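"""Seeded generators for every input kind, with planted ground truth.

Three generators emulate the statistical structure of the study inputs so
that every downstream stage is testable without any external data:

* :func:`simulate_mds` — per-site mutant-read frequency tables from an
  ultra-deep amplicon assay of two treatment arms, with a context-biased
  mutagen planted in the treated arm (fold-enrichment of chosen SBS96
  classes over a flat background), binomial sequencing noise at fixed
  consensus depth, plus sequenced-strand C>T/G>T artifact rows and
  super-threshold outlier rows to exercise the technical filters;
* :func:`simulate_tumors` — per-tumor SNV catalogs with one planted clonal
  driver per tumor (truncated-normal VAF around 0.45), subclonal passengers
  (Beta VAFs around 0.08), and germline-SNP decoys shared within genotype
  groups, together with the cancer-gene list and human-recurrence catalog
  the prioritization ladder consumes;
* :func:`simulate_exposures` — a signature matrix (Dirichlet-random
  definitions plus one concentrated "minor" signature), per-tumor exposure
  counts with a dominant signature, and a driver table whose substitution
  classes are drawn either from the dominant or from the minor signature,
  recording which.

Every generator requires an explicit seed and is byte-deterministic given
config + seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .driver_filter import RecurrenceCatalog, RecurrenceEntry
from .signature_concordance import CODON_CONTEXTS, SignatureMatrix
from .spectrum import (
    BASES,
    COMPLEMENT,
    SBS96_LABELS,
    SubstitutionClass,
    classify_substitution,
)

# Synthetic amplicon reference (invented sequence, not a genomic locus);
# interior positions provide the default MDS site set. Contains several CAA
# trinucleotides so the urethane-like T[T>A]G class is assayable.
MDS_REFERENCE = (
    "GCAATCAAGCAACTGACAAGTCCATTGGACAATGCTGTAGCAAGACTTCAATGGCCAAGTATGC"
)


def _require_seed(seed) -> np.random.Generator:
    if seed is None:
        raise ValueError("a seed is mandatory; unseeded generation is not allowed")
    return np.random.default_rng(int(seed))


def default_mds_sites(
    n_sites: int = 20, reference: str = MDS_REFERENCE, amplicon: str = "AmpliconA"
) -> list[tuple[str, int, str]]:
    """(amplicon, 1-based position, trinucleotide) sites from the reference."""
    interior = len(reference) - 2
    if n_sites > interior:
        raise ValueError(f"reference supports at most {interior} sites")
    return [
        (amplicon, pos, reference[pos - 2 : pos + 1])
        for pos in range(2, 2 + n_sites)
    ]


@dataclass
class MDSSimConfig:
    """Study conditions for the amplicon-frequency simulation."""

    seed: int
    n_animals_per_arm: int = 5
    n_sites: int = 20
    sites: Optional[Sequence[tuple[str, int, str]]] = None
    depth: int = 1_000_000
    background_rate: float = 1e-6
    enriched_classes: dict[str, float] = field(
        default_factory=lambda: {"T[T>A]G": 10.0}
    )
    arms: tuple[str, str] = ("PBS", "urethane")  # (control, treated)
    artifact_fold: float = 50.0  # sequenced-strand C>T/G>T inflation
    outlier_fraction: float = 0.01
    outlier_frequency: float = 5e-5


@dataclass
class MDSGroundTruth:
    true_rates: pd.DataFrame  # arm x 96 true per-site rates
    row_flags: pd.DataFrame  # per emitted row: is_artifact, is_outlier


def simulate_mds(config: MDSSimConfig) -> tuple[pd.DataFrame, MDSGroundTruth]:
    """Emit an MDS-dialect table: one row per animal x site x alternate base."""
    rng = _require_seed(config.seed)
    sites = (
        list(config.sites)
        if config.sites is not None
        else default_mds_sites(config.n_sites)
    )
    control, treated = config.arms

    true_rates = pd.DataFrame(
        config.background_rate,
        index=list(config.arms),
        columns=list(SBS96_LABELS),
    )
    for label, fold in config.enriched_classes.items():
        if label not in SBS96_LABELS:
            raise ValueError(f"unknown enriched class {label!r}")
        true_rates.loc[treated, label] = config.background_rate * fold

    rows = []
    flags = []
    for arm in config.arms:
        for a in range(1, config.n_animals_per_arm + 1):
            animal = f"{arm}_mouse{a}"
            for amplicon, pos, tri in sites:
                ref = tri[1]
                for alt in BASES:
                    if alt == ref:
                        continue
                    label = classify_substitution(tri, alt).label
                    rate = float(true_rates.loc[arm, label])
                    is_artifact = (ref, alt) in (("C", "T"), ("G", "T"))
                    if is_artifact:
                        rate *= config.artifact_fold
                    freq = rng.binomial(config.depth, rate) / config.depth
                    if (
                        not is_artifact
                        and config.outlier_fraction > 0
                        and rng.random() < config.outlier_fraction
                    ):
                        freq = config.outlier_frequency
                    rows.append(
                        {
                            "animal_id": animal,
                            "arm": arm,
                            "amplicon": amplicon,
                            "position": pos,
                            "ref": ref,
                            "alt": alt,
                            "context3": tri,
                            "frequency": freq,
                        }
                    )
                    flags.append(
                        {"is_artifact": is_artifact, "is_outlier": freq > 2e-5}
                    )
    table = pd.DataFrame(rows)
    gt = MDSGroundTruth(true_rates=true_rates, row_flags=pd.DataFrame(flags))
    return table, gt


# --- tumor SNV catalogs ---------------------------------------------------

#: Planted driver alleles: (gene, aa_change) -> (chrom, pos, patients in the
#: synthetic human-recurrence catalog). Coordinates are invented tokens; the
#: substitution context comes from the shared hotspot codon-context table.
DRIVER_LOCI: dict[tuple[str, str], tuple[str, int, int]] = {
    ("Kras", "Q61L"): ("chr6", 145_246_182, 300),
    ("Kras", "Q61R"): ("chr6", 145_246_182, 150),
    ("Kras", "G12D"): ("chr6", 145_246_035, 5000),
    ("Kras", "Q61H"): ("chr6", 145_246_183, 100),
    ("Braf", "V637E"): ("chr6", 39_627_909, 60_000),
}

#: Default cohort driver assignment: allele -> number of tumors (sums to 23).
DEFAULT_DRIVER_MIX: dict[tuple[str, str], int] = {
    ("Kras", "Q61L"): 6,
    ("Kras", "Q61R"): 4,
    ("Kras", "G12D"): 5,
    ("Kras", "Q61H"): 3,
    ("Braf", "V637E"): 5,
}

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class TumorSimConfig:
    """Study conditions for the tumor-catalog simulation."""

    seed: int
    driver_mix: dict[tuple[str, str], int] = field(
        default_factory=lambda: dict(DEFAULT_DRIVER_MIX)
    )
    clonal_vaf_mean: float = 0.45
    clonal_vaf_sd: float = 0.05
    passenger_rate: float = 8.0
    passenger_vaf_beta: tuple[float, float] = (2.0, 23.0)
    n_groups: int = 8
    n_decoy_snps_per_group: int = 1
    n_cancer_genes: int = 460
    n_passenger_genes: int = 600
    n_recurrent_passenger_genes: int = 40

    @property
    def n_tumors(self) -> int:
        return sum(self.driver_mix.values())


@dataclass
class TumorGroundTruth:
    drivers: pd.DataFrame  # planted driver rows (sample, gene, aa_change, ...)
    decoys: pd.DataFrame  # planted germline-SNP decoy rows


@dataclass
class TumorBundle:
    """Everything the driver ladder consumes, plus the planted truth."""

    snvs: pd.DataFrame
    gene_list: list[str]
    recurrence: pd.DataFrame
    ground_truth: TumorGroundTruth


def _truncnorm01(rng: np.random.Generator, mean: float, sd: float) -> float:
    # rejection sampling; (0, 1) open interval
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if 0.0 < v < 1.0:
            return float(v)
    raise RuntimeError("truncated-normal sampling failed")


def _seq_strand_from_class(
    rng: np.random.Generator, label: str
) -> tuple[str, str, str]:
    """(ref, alt, tri) on a random strand realizing the given class."""
    c = SubstitutionClass.from_label(label)
    tri = c.five_prime + c.ref + c.three_prime
    if rng.random() < 0.5:
        return c.ref, c.alt, tri
    rc = "".join(COMPLEMENT[b] for b in reversed(tri))
    return COMPLEMENT[c.ref], COMPLEMENT[c.alt], rc


def simulate_tumors(config: TumorSimConfig) -> TumorBundle:
    """Emit a cohort SNV catalog with planted drivers, passengers and decoys.

    Each tumor carries exactly one clonal driver from ``driver_mix`` and a
    Poisson number of subclonal passengers in invented genes. Driver alleles
    are spread across genotype groups so that no identical driver SNV recurs
    within a group (recurrent hotspot drivers must not look like shared
    germline SNPs to the cohort filter). Decoy SNPs recur across a whole
    group at VAF ~0.5 or 1.0.
    """
    rng = _require_seed(config.seed)

    # genes: curated cancer list + invented passenger pool
    cancer_genes = ["Kras", "Braf", "Trp53", "Ctnnb1", "Spen"] + [
        f"GENE{i:04d}" for i in range(1, config.n_cancer_genes - 4)
    ]
    passenger_genes = [f"GENE{i:04d}" for i in range(1, config.n_passenger_genes + 1)]

    # recurrence catalog: hotspot drivers + a sprinkling of recurrent
    # passenger genes (positions 1..400, 5-30 patients)
    rec_rows = []
    for (gene, aa), (_, _, patients) in DRIVER_LOCI.items():
        rec_rows.append(
            {
                "mouse_gene": gene,
                "human_gene": gene.upper(),
                "aa_position": int(aa[1:-1]),
                "aa_change": aa,
                "patient_count": patients,
            }
        )
    rec_gene_pick = rng.choice(
        passenger_genes, size=config.n_recurrent_passenger_genes, replace=False
    )
    for g in rec_gene_pick:
        rec_rows.append(
            {
                "mouse_gene": g,
                "human_gene": g.upper(),
                "aa_position": int(rng.integers(1, 401)),
                "aa_change": f"{_AA[rng.integers(20)]}{rng.integers(1, 401)}"
                f"{_AA[rng.integers(20)]}",
                "patient_count": int(rng.integers(5, 31)),
            }
        )
    recurrence = pd.DataFrame(rec_rows)

    # tumors, allele-major; allele i-th tumor goes to group i (distinct)
    tumors: list[tuple[str, str, str, str]] = []  # (sample, gene, aa, group)
    t = 0
    for (gene, aa), n in config.driver_mix.items():
        if n > config.n_groups:
            raise ValueError(
                f"driver {gene} {aa} count {n} exceeds n_groups={config.n_groups}; "
                "identical drivers would recur within a genotype group"
            )
        for i in range(n):
            t += 1
            tumors.append((f"T{t:02d}", gene, aa, f"G{i + 1}"))
    rng.shuffle(tumors)

    snv_rows = []
    truth_rows = []
    for sample, gene, aa, group in tumors:
        chrom, pos, _ = DRIVER_LOCI[(gene, aa)]
        tri, alt = CODON_CONTEXTS[(gene.upper(), aa)]
        vaf = _truncnorm01(rng, config.clonal_vaf_mean, config.clonal_vaf_sd)
        row = {
            "sample": sample,
            "chrom": chrom,
            "pos": pos,
            "ref": tri[1],
            "alt": alt,
            "context3": tri,
            "gene": gene,
            "effect": "missense",
            "aa_change": aa,
            "vaf": round(vaf, 4),
            "group": group,
        }
        snv_rows.append(row)
        truth_rows.append({**row, "role": "driver"})

        a, b = config.passenger_vaf_beta
        for _ in range(rng.poisson(config.passenger_rate)):
            label = SBS96_LABELS[rng.integers(96)]
            ref, palt, ptri = _seq_strand_from_class(rng, label)
            pgene = passenger_genes[rng.integers(len(passenger_genes))]
            effect = ["missense", "missense", "missense", "missense",
                      "synonymous", "other"][rng.integers(6)]
            pvaf = float(np.clip(rng.beta(a, b), 1e-4, 0.9999))
            snv_rows.append(
                {
                    "sample": sample,
                    "chrom": f"chr{rng.integers(1, 20)}",
                    "pos": int(rng.integers(10_000, 150_000_000)),
                    "ref": ref,
                    "alt": palt,
                    "context3": ptri,
                    "gene": pgene,
                    "effect": effect,
                    "aa_change": f"{_AA[rng.integers(20)]}{rng.integers(1, 501)}"
                    f"{_AA[rng.integers(20)]}",
                    "vaf": round(pvaf, 4),
                    "group": group,
                }
            )

    # germline decoys: one shared SNV per group with >= 2 tumors
    decoy_rows = []
    groups: dict[str, list[str]] = {}
    for sample, _, _, group in tumors:
        groups.setdefault(group, []).append(sample)
    for gi, (group, samples) in enumerate(sorted(groups.items())):
        if len(samples) < 2:
            continue
        for d in range(config.n_decoy_snps_per_group):
            label = SBS96_LABELS[rng.integers(96)]
            ref, dalt, dtri = _seq_strand_from_class(rng, label)
            chrom = f"chr{rng.integers(1, 20)}"
            pos = int(rng.integers(10_000, 150_000_000))
            vaf = 1.0 if rng.random() < 0.5 else round(rng.normal(0.5, 0.02), 4)
            for sample in samples:
                row = {
                    "sample": sample,
                    "chrom": chrom,
                    "pos": pos,
                    "ref": ref,
                    "alt": dalt,
                    "context3": dtri,
                    "gene": passenger_genes[rng.integers(len(passenger_genes))],
                    "effect": "missense",
                    "aa_change": f"{_AA[rng.integers(20)]}{rng.integers(1, 501)}"
                    f"{_AA[rng.integers(20)]}",
                    "vaf": vaf,
                    "group": group,
                }
                snv_rows.append(row)
                decoy_rows.append(row)

    snvs = pd.DataFrame(snv_rows).sort_values(
        ["sample", "chrom", "pos", "alt"], kind="mergesort"
    )
    snvs = snvs.reset_index(drop=True)
    truth = TumorGroundTruth(
        drivers=pd.DataFrame(truth_rows), decoys=pd.DataFrame(decoy_rows)
    )
    return TumorBundle(
        snvs=snvs,
        gene_list=cancer_genes,
        recurrence=recurrence,
        ground_truth=truth,
    )


def recurrence_catalog_from_frame(df: pd.DataFrame) -> RecurrenceCatalog:
    """Build the ladder's lookup structure from the TSV-dialect frame."""
    return RecurrenceCatalog(
        RecurrenceEntry(
            gene=str(r.mouse_gene),
            human_gene=str(r.human_gene),
            aa_position=int(r.aa_position),
            aa_change=str(r.aa_change),
            patient_count=int(r.patient_count),
        )
        for r in df.itertuples(index=False)
    )


# --- signature exposures --------------------------------------------------


@dataclass
class ExposureSimConfig:
    """Study conditions for the signature-exposure simulation."""

    seed: int
    n_tumors: int = 100
    n_signatures: int = 5
    dirichlet_alpha: float = 0.5
    dominant_share: float = 0.9
    minor_share: float = 0.05
    minor_fraction: float = 0.0  # fraction of tumors with minor-origin drivers
    total_mutations: tuple[int, int] = (100, 500)
    signature_matrix: Optional[SignatureMatrix] = None


@dataclass
class ExposureGroundTruth:
    assignments: pd.DataFrame  # per tumor: dominant sig, origin, driver class


def simulate_exposures(
    config: ExposureSimConfig,
) -> tuple[SignatureMatrix, pd.DataFrame, pd.DataFrame, ExposureGroundTruth]:
    """Emit (signature matrix, exposure counts, driver table, ground truth).

    Signature definitions are symmetric-Dirichlet draws plus one designated
    minor signature ("SBSminor") concentrating 90% of its mass on the class
    least producible by the random signatures. Per tumor, one random
    signature dominates the exposures; the driver's substitution class is
    drawn from the dominant signature, or — for minor-origin tumors — set to
    the minor signature's peak class with the minor signature planted at a
    small fixed exposure share.
    """
    rng = _require_seed(config.seed)
    if config.signature_matrix is not None:
        sigs = config.signature_matrix
        names = [s for s in sigs.signatures if s != "SBSminor"]
        if "SBSminor" not in sigs.signatures:
            raise ValueError("supplied signature matrix needs an 'SBSminor' column")
    else:
        names = [f"SBS{i + 1}" for i in range(config.n_signatures)]
        S = pd.DataFrame(
            rng.dirichlet(np.full(96, config.dirichlet_alpha), size=len(names)).T,
            index=list(SBS96_LABELS),
            columns=names,
        )
        target = S.mean(axis=1).idxmin()
        minor = pd.Series(0.1 / 95, index=list(SBS96_LABELS))
        minor[target] = 0.0
        minor = minor / minor.sum() * 0.1
        minor[target] = 0.9
        S["SBSminor"] = minor
        sigs = SignatureMatrix(S)
    minor_peak = sigs.S["SBSminor"].idxmax()

    n_minor = int(round(config.minor_fraction * config.n_tumors))
    origins = np.array(["minor"] * n_minor + ["dominant"] * (config.n_tumors - n_minor))
    rng.shuffle(origins)

    exp_rows, drv_rows, truth_rows = [], [], []
    for i, origin in enumerate(origins):
        tid = f"DO{i + 1:04d}"
        dom = names[rng.integers(len(names))]
        others = [s for s in sigs.signatures if s != dom]
        rest = rng.dirichlet(np.ones(len(others)))
        shares = pd.Series(0.0, index=sigs.signatures)
        shares[dom] = config.dominant_share
        shares[others] = (1.0 - config.dominant_share) * rest
        if origin == "minor":
            # fix the minor signature's share, rescale the other non-dominant
            non = [s for s in others if s != "SBSminor"]
            scale = 1.0 - config.dominant_share - config.minor_share
            shares["SBSminor"] = config.minor_share
            tot = shares[non].sum()
            shares[non] = shares[non] / tot * scale if tot > 0 else scale / len(non)
            driver_class = minor_peak
            source = "SBSminor"
        else:
            probs = sigs.S[dom].values
            driver_class = SBS96_LABELS[rng.choice(96, p=probs / probs.sum())]
            source = dom
        total = int(rng.integers(*config.total_mutations))
        exp_rows.append({"tumor_id": tid, **(shares * total).round(3).to_dict()})
        drv_rows.append(
            {
                "tumor_id": tid,
                "gene": "KRAS",
                "aa_change": "synthetic",
                "substitution_class": driver_class,
            }
        )
        truth_rows.append(
            {
                "tumor_id": tid,
                "dominant_signature": dom,
                "driver_origin": origin,
                "driver_source_signature": source,
                "driver_class": driver_class,
            }
        )

    exposures = pd.DataFrame(exp_rows).set_index("tumor_id")
    drivers = pd.DataFrame(drv_rows)
    truth = ExposureGroundTruth(assignments=pd.DataFrame(truth_rows))
    return sigs, exposures, drivers, truth
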