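"""Readers/writers for every table dialect, run configuration, and run-all.

Canonical interchange is header-ed TSV (the upstream callers end in annotated
variant tables, not VCF); a minimal VCF reader is provided for convenience.
All writers emit deterministic column order and row sort so that re-running a
configuration reproduces outputs byte-for-byte.

Dialects:

* MDS table — TSV: animal_id, arm, amplicon, position, ref, alt, context3,
  frequency (sequenced-strand representation);
* SNV catalog — TSV: sample, chrom, pos, ref, alt, context3, gene, effect,
  aa_change, vaf, group (VAF accepted as fraction or percent, auto-detected);
  or a minimal VCF with SAMPLE/GENE/AA/EFFECT/CONTEXT/VAF/GROUP INFO keys;
* signature matrix — COSMIC SBS TSV: a "Type" column of "A[C>A]A"-style
  labels plus one column per signature;
* exposures — CSV: one row per sample, one count column per signature;
* spectrum — TSV: class, value (96 rows, COSMIC order);
* gene list — one symbol per line; recurrence catalog — TSV: mouse_gene,
  human_gene, aa_position, aa_change, patient_count; known SNPs — TSV:
  chrom, pos, ref, alt.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .driver_filter import (
    EFFECTS,
    FilterConfig,
    LadderResult,
    RecurrenceCatalog,
    SNVRecord,
    run_driver_ladder,
)
from .optimality import RATIO_EPSILON, build_optimality_table, score_candidates
from .signature_concordance import SignatureMatrix, concordance_table
from .spectrum import (
    SBS96_LABELS,
    MDSSiteObservation,
    MutationSpectrum,
    build_mds_spectrum,
    build_wes_spectrum,
    filter_mds_artifacts,
)
from .synthetic_data import recurrence_catalog_from_frame

logger = logging.getLogger("mutopt")


class FormatError(ValueError):
    """Raised for malformed or incomplete input tables."""


def _read_table(path: str | Path, sep: str, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file") from None
    if df.empty:
        raise FormatError(f"{path}: no data rows")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return df


def _numeric(df: pd.DataFrame, col: str, path) -> pd.Series:
    vals = pd.to_numeric(df[col], errors="coerce")
    if vals.isna().any():
        row = int(vals.index[vals.isna()][0]) + 2  # header + 1-based
        raise FormatError(f"{path}: non-numeric value in column {col!r} at line {row}")
    return vals


# --- MDS tables -----------------------------------------------------------

MDS_COLUMNS = [
    "animal_id", "arm", "amplicon", "position", "ref", "alt", "context3",
    "frequency",
]


def read_mds_table(path: str | Path) -> list[MDSSiteObservation]:
    df = _read_table(path, "\t", MDS_COLUMNS)
    _numeric(df, "position", path)
    _numeric(df, "frequency", path)
    return [
        MDSSiteObservation(
            animal_id=str(r.animal_id),
            arm=str(r.arm),
            amplicon=str(r.amplicon),
            position=int(r.position),
            ref=str(r.ref),
            alt=str(r.alt),
            tri_context=str(r.context3),
            frequency=float(r.frequency),
        )
        for r in df.itertuples(index=False)
    ]


def write_mds_table(table: pd.DataFrame, path: str | Path) -> None:
    table[MDS_COLUMNS].to_csv(path, sep="\t", index=False)


# --- SNV catalogs ---------------------------------------------------------

SNV_COLUMNS = [
    "sample", "chrom", "pos", "ref", "alt", "context3", "gene", "effect",
    "aa_change", "vaf", "group",
]


def _normalize_vaf(vals: pd.Series, path) -> pd.Series:
    if (vals > 1.0).any():
        logger.info("%s: VAF column looks like percent; dividing by 100", path)
        vals = vals / 100.0
    return vals


def read_snv_table(path: str | Path) -> list[SNVRecord]:
    """Read a tumor SNV catalog from TSV (or minimal VCF by extension)."""
    path = Path(path)
    if path.suffix.lower() == ".vcf":
        return _read_snv_vcf(path)
    df = _read_table(path, "\t", [c for c in SNV_COLUMNS if c not in ("effect", "group")])
    if "effect" not in df.columns:
        df["effect"] = "missense"
    if "group" not in df.columns:
        df["group"] = ""
    _numeric(df, "pos", path)
    vafs = _normalize_vaf(_numeric(df, "vaf", path), path)
    records = []
    for i, r in enumerate(df.itertuples(index=False)):
        effect = str(r.effect)
        if effect not in EFFECTS:
            raise FormatError(f"{path}: unknown effect {effect!r} at line {i + 2}")
        records.append(
            SNVRecord(
                sample_id=str(r.sample),
                chrom=str(r.chrom),
                pos=int(r.pos),
                ref=str(r.ref),
                alt=str(r.alt),
                tri_context=str(r.context3),
                gene=str(r.gene),
                effect=effect,
                aa_change=str(r.aa_change),
                vaf=float(vafs.iloc[i]),
                group_label="" if pd.isna(r.group) else str(r.group),
            )
        )
    return records


def _read_snv_vcf(path: Path) -> list[SNVRecord]:
    """Minimal VCF: per-record SAMPLE/GENE/AA/EFFECT/CONTEXT/VAF[/GROUP] INFO keys."""
    records = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 8:
                raise FormatError(f"{path}: truncated VCF record at line {ln}")
            chrom, pos, _, ref, alt = parts[0], parts[1], parts[2], parts[3], parts[4]
            info = dict(
                kv.split("=", 1) for kv in parts[7].split(";") if "=" in kv
            )
            try:
                vaf = float(info["VAF"])
            except (KeyError, ValueError):
                raise FormatError(f"{path}: missing/invalid VAF at line {ln}") from None
            if vaf > 1.0:
                vaf /= 100.0
            records.append(
                SNVRecord(
                    sample_id=info.get("SAMPLE", "S1"),
                    chrom=chrom,
                    pos=int(pos),
                    ref=ref,
                    alt=alt,
                    tri_context=info["CONTEXT"],
                    gene=info.get("GENE", ""),
                    effect=info.get("EFFECT", "missense"),
                    aa_change=info.get("AA", ""),
                    vaf=vaf,
                    group_label=info.get("GROUP", ""),
                )
            )
    if not records:
        raise FormatError(f"{path}: no VCF records")
    return records


def write_snv_table(table: pd.DataFrame, path: str | Path) -> None:
    df = table.rename(columns={"sample_id": "sample", "group_label": "group"})
    df = df[SNV_COLUMNS].sort_values(
        ["sample", "chrom", "pos", "alt"], kind="mergesort"
    )
    df.to_csv(path, sep="\t", index=False)


def snv_records_to_frame(records: Sequence[SNVRecord]) -> pd.DataFrame:
    rows = [
        {
            "sample": s.sample_id, "chrom": s.chrom, "pos": s.pos, "ref": s.ref,
            "alt": s.alt, "context3": s.tri_context, "gene": s.gene,
            "effect": s.effect, "aa_change": s.aa_change, "vaf": s.vaf,
            "group": s.group_label,
        }
        for s in records
    ]
    return pd.DataFrame(rows, columns=SNV_COLUMNS)


# --- spectra --------------------------------------------------------------


def write_spectrum(spectrum: MutationSpectrum, path: str | Path) -> None:
    spectrum.to_frame().to_csv(path, sep="\t", index=False)


def read_spectrum(path: str | Path, kind: str = "mean_frequency") -> MutationSpectrum:
    df = _read_table(path, "\t", ["class", "value"])
    _numeric(df, "value", path)
    values = pd.Series(df["value"].values, index=df["class"].values, dtype=float)
    n_units = len(df)
    return MutationSpectrum(values, kind, n_units=n_units)


# --- signatures and exposures --------------------------------------------


def read_signature_matrix(path: str | Path) -> SignatureMatrix:
    """COSMIC SBS TSV: 'Type' label column + one probability column per signature.

    Columns summing to 1 within 1e-4 pass; within 1e-2 they are renormalized
    with a warning; anything further off is rejected.
    """
    df = _read_table(path, "\t", ["Type"])
    df = df.set_index("Type")
    missing = set(SBS96_LABELS) - set(df.index)
    if missing:
        raise FormatError(f"{path}: signature matrix missing {len(missing)} classes")
    df = df.reindex(SBS96_LABELS).astype(float)
    for col in df.columns:
        total = float(df[col].sum())
        if abs(total - 1.0) <= 1e-4:
            df[col] = df[col] / total
        elif abs(total - 1.0) <= 1e-2:
            logger.warning(
                "%s: signature %s sums to %.4f; renormalized", path, col, total
            )
            df[col] = df[col] / total
        else:
            raise FormatError(
                f"{path}: signature {col} sums to {total:.4f}, outside tolerance"
            )
    return SignatureMatrix(df)


def write_signature_matrix(sigs: SignatureMatrix, path: str | Path) -> None:
    out = sigs.S.copy()
    out.insert(0, "Type", out.index)
    out.to_csv(path, sep="\t", index=False)


def read_exposures(path: str | Path) -> pd.DataFrame:
    """Per-sample signature exposure counts (CSV); all-zero samples dropped."""
    df = _read_table(path, ",", [])
    df = df.set_index(df.columns[0])
    df = df.astype(float)
    if (df.values < 0).any():
        raise FormatError(f"{path}: negative exposure counts")
    zero = df.sum(axis=1) == 0
    if zero.any():
        logger.warning(
            "%s: %d all-zero sample(s) skipped: %s",
            path, int(zero.sum()), list(df.index[zero]),
        )
        df = df[~zero]
    return df


def write_exposures(exposures: pd.DataFrame, path: str | Path) -> None:
    out = exposures.sort_index()
    out.index.name = out.index.name or "tumor_id"
    out.to_csv(path)


# --- small auxiliary lists ------------------------------------------------


def read_gene_list(path: str | Path) -> list[str]:
    genes = [
        line.strip()
        for line in Path(path).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]
    if not genes:
        raise FormatError(f"{path}: empty gene list")
    return genes


def write_gene_list(genes: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(genes) + "\n")


RECURRENCE_COLUMNS = [
    "mouse_gene", "human_gene", "aa_position", "aa_change", "patient_count",
]


def read_recurrence(path: str | Path) -> RecurrenceCatalog:
    df = _read_table(path, "\t", RECURRENCE_COLUMNS)
    _numeric(df, "aa_position", path)
    _numeric(df, "patient_count", path)
    return recurrence_catalog_from_frame(df)


def write_recurrence(df: pd.DataFrame, path: str | Path) -> None:
    df[RECURRENCE_COLUMNS].sort_values(
        ["mouse_gene", "aa_position", "aa_change"], kind="mergesort"
    ).to_csv(path, sep="\t", index=False)


def read_known_snps(path: str | Path) -> set[tuple[str, int]]:
    df = _read_table(path, "\t", ["chrom", "pos"])
    _numeric(df, "pos", path)
    return {(str(r.chrom), int(r.pos)) for r in df.itertuples(index=False)}


# --- run configuration and orchestration ---------------------------------

_RUNCONFIG_KEYS = {
    "mds", "snv", "genes", "recurrence", "known_snps", "signatures",
    "exposures", "drivers", "outdir", "seed", "log_level", "control_arm",
    "treated_arm", "outlier_threshold", "ratio_epsilon", "burden_mode",
    "filter",
}


@dataclass
class RunConfig:
    """Paths and threshold overrides for an end-to-end run."""

    outdir: str
    mds: Optional[str] = None
    snv: Optional[str] = None
    genes: Optional[str] = None
    recurrence: Optional[str] = None
    known_snps: Optional[str] = None
    signatures: Optional[str] = None
    exposures: Optional[str] = None
    drivers: Optional[str] = None  # pre-joined driver table for concordance
    seed: int = 0
    log_level: str = "INFO"
    control_arm: str = "PBS"
    treated_arm: str = "urethane"
    outlier_threshold: float = 2e-5
    ratio_epsilon: float = RATIO_EPSILON
    burden_mode: str = "weighted"
    filter: FilterConfig = field(default_factory=FilterConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - _RUNCONFIG_KEYS
        if unknown:
            raise FormatError(f"{path}: unknown config key(s) {sorted(unknown)}")
        fc = raw.pop("filter", {})
        fc_fields = {f.name for f in dataclasses.fields(FilterConfig)}
        bad = set(fc) - fc_fields
        if bad:
            raise FormatError(f"{path}: unknown filter key(s) {sorted(bad)}")
        if "vaf_band" in fc and fc["vaf_band"] is not None:
            fc["vaf_band"] = tuple(fc["vaf_band"])
        if "rel_band" in fc:
            fc["rel_band"] = tuple(fc["rel_band"])
        if "reference_genes" in fc:
            fc["reference_genes"] = tuple(fc["reference_genes"])
        cfg = cls(filter=FilterConfig(**fc), **raw)
        for key in ("mds", "snv", "genes", "recurrence", "known_snps",
                    "signatures", "exposures", "drivers"):
            p = getattr(cfg, key)
            if p is not None and not Path(p).exists():
                raise FormatError(f"{path}: referenced path does not exist: {p}")
        return cfg


def run_all(config: RunConfig) -> dict:
    """Execute spectrum -> optimality -> drivers -> concordance where inputs permit.

    Writes per-stage TSVs plus a manifest into ``config.outdir`` and returns
    the manifest. Stage failures are recorded in the manifest and re-raised
    after partial outputs are flushed.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "inputs": {
            k: getattr(config, k)
            for k in ("mds", "snv", "genes", "recurrence", "known_snps",
                      "signatures", "exposures", "drivers")
            if getattr(config, k)
        },
        "thresholds": {
            "outlier_threshold": config.outlier_threshold,
            "ratio_epsilon": config.ratio_epsilon,
            "burden_mode": config.burden_mode,
            "filter": dataclasses.asdict(config.filter),
        },
        "stages": {},
    }
    failure: Optional[Exception] = None
    spectra = {}
    ladder: Optional[LadderResult] = None

    try:
        if config.mds:
            obs = filter_mds_artifacts(
                read_mds_table(config.mds), config.outlier_threshold
            )
            for arm in (config.control_arm, config.treated_arm):
                spec = build_mds_spectrum([o for o in obs if o.arm == arm], arm)
                spectra[arm] = spec
                write_spectrum(spec, outdir / f"spectrum_{arm}.tsv")
            manifest["stages"]["spectrum_mds"] = "ok"
        if config.snv:
            snvs = read_snv_table(config.snv)
            wes = build_wes_spectrum(
                (s.sample_id, s.substitution_class) for s in snvs
            )
            write_spectrum(wes, outdir / "spectrum_wes.tsv")
            manifest["stages"]["spectrum_wes"] = "ok"

        if config.snv and config.genes and config.recurrence:
            known = read_known_snps(config.known_snps) if config.known_snps else None
            ladder = run_driver_ladder(
                read_snv_table(config.snv),
                read_gene_list(config.genes),
                read_recurrence(config.recurrence),
                config.filter,
                known,
            )
            ladder.to_frame().to_csv(outdir / "drivers.tsv", sep="\t", index=False)
            trail_rows = [
                {
                    "sample_id": c.snv.sample_id, "chrom": c.snv.chrom,
                    "pos": c.snv.pos, "alt": c.snv.alt, "tier": c.tier,
                    "stage": st, "passed": ok, "reason": why,
                }
                for c in ladder.all_candidates
                for st, ok, why in c.trail
            ]
            pd.DataFrame(trail_rows).to_csv(
                outdir / "driver_trail.tsv", sep="\t", index=False
            )
            manifest["stages"]["drivers"] = "ok"
            manifest["vaf_band"] = list(ladder.vaf_band)

        if spectra and ladder is not None:
            table = build_optimality_table(
                spectra[config.treated_arm],
                spectra[config.control_arm],
                config.ratio_epsilon,
            )
            table.rename_axis("class").to_csv(outdir / "optimality.tsv", sep="\t")
            scored = score_candidates(ladder.to_frame(), table)
            scored.to_csv(outdir / "scored_drivers.tsv", sep="\t", index=False)
            manifest["stages"]["optimality"] = "ok"
            manifest["concordance_rule"] = (
                "carcinogen-concordant iff delta_score > pbs_score "
                "(identity-line convention)"
            )

        if config.signatures and config.exposures and config.drivers:
            sigs = read_signature_matrix(config.signatures)
            exposures = read_exposures(config.exposures)
            drv = _read_table(config.drivers, "\t", ["tumor_id"])
            conc = concordance_table(
                exposures, sigs, drv, burden_mode=config.burden_mode
            )
            conc.to_csv(outdir / "concordance.tsv", sep="\t", index=False)
            manifest["stages"]["concordance"] = "ok"
    except Exception as exc:  # partial outputs retained; manifest notes failure
        failure = exc
        manifest["stages"]["failed"] = f"{type(exc).__name__}: {exc}"

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    if failure is not None:
        raise failure
    return manifest
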