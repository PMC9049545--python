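"""Per-tumor concordance between mutational signatures and the driver mutation.

Given COSMIC-style SBS signature definitions (96-class probability vectors)
and per-tumor signature exposures (mutation counts attributed to each
signature by refitting), this module asks: *does the tumor's driver mutation
look like a product of the mutational processes active in that tumor?*

For one tumor with exposures :math:`E_k` and signature definitions
:math:`S_{k,c}` (class :math:`c` probability under signature :math:`k`):

1. exposures are normalized to proportions :math:`p_k = E_k / \\sum_j E_j`;
2. the contribution of each signature to each class is
   :math:`w_{k,c} = p_k S_{k,c} / \\sum_j p_j S_{j,c}` (column-normalized so
   the signatures' shares of every class sum to 1);
3. the tumor's expected class burden is
   :math:`b_c \\propto \\sum_k E_k w_{k,c}`, normalized over classes (the
   default, literal reading; ``mode="simple"`` uses the algebraically
   natural :math:`b_c \\propto \\sum_k E_k S_{k,c}` instead).

The **concordance score** is :math:`b` at the driver's substitution class —
the estimated fraction of the tumor's burden falling on that class. The
**mismatch score** is :math:`w_{k^*,c^*} - p_{k^*}` where :math:`k^*` is the
signature contributing most to the driver class :math:`c^*`: near 0 when the
dominant process explains the driver, large when a minor process does.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .spectrum import SBS96_LABELS, SubstitutionClass, classify_substitution

logger = logging.getLogger("mutopt")


@dataclass
class SignatureMatrix:
    """Signature definitions: 96-class probability vectors per signature.

    ``S`` is a DataFrame indexed by the 96 class labels (COSMIC row order),
    one column per signature; every column sums to 1.
    """

    S: pd.DataFrame

    def __post_init__(self) -> None:
        S = self.S.reindex(SBS96_LABELS)
        if S.isna().any().any():
            missing = set(SBS96_LABELS) - set(self.S.index)
            raise ValueError(f"signature matrix missing classes: {sorted(missing)[:4]}")
        if (S.values < 0).any():
            raise ValueError("signature matrix contains negative probabilities")
        sums = S.sum(axis=0)
        if (np.abs(sums - 1.0) > 1e-6).any():
            bad = sums[np.abs(sums - 1.0) > 1e-6]
            raise ValueError(f"signature columns do not sum to 1: {dict(bad.round(4))}")
        self.S = S

    @property
    def signatures(self) -> list[str]:
        return list(self.S.columns)


def signature_proportions(exposures: pd.Series) -> Optional[pd.Series]:
    """Normalize a tumor's per-signature mutation counts to proportions.

    Returns None (with a warning) for all-zero exposure vectors — such
    tumors cannot be analyzed.
    """
    E = pd.Series(exposures, dtype=float)
    if (E < 0).any():
        raise ValueError("exposures must be >= 0")
    total = float(E.sum())
    if total == 0.0:
        warnings.warn(f"all-zero exposures for {E.name!r}; tumor skipped")
        return None
    return E / total


def substitution_contributions(p: pd.Series, sigs: SignatureMatrix) -> pd.DataFrame:
    """Per-signature share of each substitution class, column-normalized.

    Returns a (signatures x 96) DataFrame ``w`` with each defined column
    summing to 1; classes no active signature can produce are NaN.
    """
    missing = set(p.index) - set(sigs.signatures)
    if missing:
        raise ValueError(f"exposures name unknown signatures: {sorted(missing)}")
    S = sigs.S[list(p.index)]  # 96 x k
    raw = S.mul(p, axis=1)  # p_k * S_{k,c}
    denom = raw.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = raw.div(denom, axis=0)
    w[denom == 0.0] = np.nan
    return w.T  # signatures x 96


def burden_proportions(
    E: pd.Series,
    w: pd.DataFrame,
    sigs: Optional[SignatureMatrix] = None,
    mode: str = "weighted",
) -> Optional[pd.Series]:
    """Estimated per-class proportion of the tumor's mutation burden.

    ``mode="weighted"`` (default): raw_c = sum_k E_k * w_{k,c}, then
    normalized over classes. ``mode="simple"``: raw_c = sum_k E_k * S_{k,c}
    (requires ``sigs``). Returns None if the raw burden is all zero.
    """
    if mode == "weighted":
        raw = w.mul(E, axis=0).sum(axis=0, skipna=True)
        raw = raw.fillna(0.0)
    elif mode == "simple":
        if sigs is None:
            raise ValueError("mode='simple' needs the signature matrix")
        raw = sigs.S[list(E.index)].mul(E, axis=1).sum(axis=1)
    else:
        raise ValueError(f"unknown burden mode {mode!r}")
    total = float(raw.sum())
    if total == 0.0:
        warnings.warn("all-zero estimated burden; tumor skipped")
        return None
    return raw / total


def concordance_score(b: pd.Series, driver_class: SubstitutionClass | str) -> float:
    """The estimated burden proportion on the driver's substitution class."""
    lab = (
        driver_class.label
        if isinstance(driver_class, SubstitutionClass)
        else str(driver_class)
    )
    if lab not in b.index:
        raise KeyError(f"unknown substitution class {lab!r}")
    return float(b[lab])


def mismatch_score(
    w: pd.DataFrame, p: pd.Series, driver_class: SubstitutionClass | str
) -> tuple[Optional[str], Optional[float]]:
    """(top signature at the driver class, its class share minus overall share).

    The top signature is the argmax over ``w`` at the driver class (ties
    broken lexicographically, logged). Returns (None, None) when no active
    signature can produce the class.
    """
    lab = (
        driver_class.label
        if isinstance(driver_class, SubstitutionClass)
        else str(driver_class)
    )
    col = w[lab]
    if col.isna().all():
        warnings.warn(f"driver class {lab} unreachable by active signatures")
        return None, None
    best = col.max()
    ties = sorted(col.index[col == best])
    if len(ties) > 1:
        logger.info("mismatch argmax tie at %s among %s; lexicographic pick", lab, ties)
    k_star = ties[0]
    return k_star, float(col[k_star] - p[k_star])


# --- driver protein change -> substitution class -------------------------

#: Coding-strand cDNA substitution contexts for hotspot driver mutations,
#: (gene, aa_change) -> (trinucleotide context, alt base). Flank bases were
#: derived from the reference CDS (KRAS codons 11-13 GCT GGT GGC, 19-20
#: TTG ACG, 60-62 GGT CAA GAG; BRAF codon 600 GTG). Mouse Kras/Braf hotspot
#: codons match the human contexts within these windows; mouse Braf V637E is
#: the equivalent of human BRAF V600E (c.1909 GTG -> GAG on the coding
#: strand). KRAS Q61H is frozen as the c.183A>T allele; the A>C allele is
#: listed under "Q61H_ac".
CODON_CONTEXTS: dict[tuple[str, str], tuple[str, str]] = {
    ("KRAS", "G12S"): ("TGG", "A"),  # c.34G>A
    ("KRAS", "G12C"): ("TGG", "T"),  # c.34G>T
    ("KRAS", "G12D"): ("GGT", "A"),  # c.35G>A
    ("KRAS", "G12V"): ("GGT", "T"),  # c.35G>T
    ("KRAS", "G12A"): ("GGT", "C"),  # c.35G>C
    ("KRAS", "G13C"): ("TGG", "T"),  # c.37G>T
    ("KRAS", "G13D"): ("GGC", "A"),  # c.38G>A
    ("KRAS", "G13V"): ("GGC", "T"),  # c.38G>T
    ("KRAS", "L19F"): ("TGA", "T"),  # c.57G>T
    ("KRAS", "Q61K"): ("TCA", "A"),  # c.181C>A
    ("KRAS", "Q61L"): ("CAA", "T"),  # c.182A>T
    ("KRAS", "Q61R"): ("CAA", "G"),  # c.182A>G
    ("KRAS", "Q61H"): ("AAG", "T"),  # c.183A>T
    ("KRAS", "Q61H_ac"): ("AAG", "C"),  # c.183A>C
    ("BRAF", "V600E"): ("GTG", "A"),  # c.1799T>A
    ("BRAF", "V637E"): ("GTG", "A"),  # mouse equivalent, c.1909T>A
}


def map_driver_to_class(
    gene: str,
    aa_change: str,
    codon_context_table: Optional[Mapping[tuple[str, str], tuple[str, str]]] = None,
) -> SubstitutionClass:
    """Canonical SBS96 class of a hotspot driver's underlying cDNA substitution.

    Gene symbols are matched case-insensitively, so mouse ``Kras`` and human
    ``KRAS`` share entries. Unknown drivers raise with the known labels.
    """
    table = codon_context_table if codon_context_table is not None else CODON_CONTEXTS
    key = (gene.upper(), aa_change)
    if key not in table:
        known = sorted({f"{g} {a}" for g, a in table})
        raise KeyError(f"unknown driver {gene} {aa_change}; known: {known}")
    tri, alt = table[key]
    return classify_substitution(tri, alt)


@dataclass
class ConcordanceResult:
    """Per-tumor concordance analysis of one driver mutation."""

    tumor_id: str
    driver_label: str
    driver_class: str
    w_driver: pd.Series  # per-signature share of the driver class
    burden: pd.Series  # 96-vector b
    concordance_score: float
    top_signature: Optional[str]
    mismatch_score: Optional[float]
    class_unreachable: bool = False


def analyze_tumor(
    tumor_id: str,
    exposures: pd.Series,
    sigs: SignatureMatrix,
    gene: str,
    aa_change: str,
    burden_mode: str = "weighted",
    codon_context_table: Optional[Mapping] = None,
    driver_class: Optional[SubstitutionClass | str] = None,
) -> Optional[ConcordanceResult]:
    """Full concordance computation for one tumor; None if unanalyzable.

    ``driver_class`` may be supplied directly (e.g. from an annotated SNV),
    otherwise it is looked up from the hotspot codon-context table.
    """
    p = signature_proportions(exposures.rename(tumor_id))
    if p is None:
        return None
    if driver_class is None:
        cls = map_driver_to_class(gene, aa_change, codon_context_table)
        lab = cls.label
    else:
        lab = (
            driver_class.label
            if isinstance(driver_class, SubstitutionClass)
            else str(driver_class)
        )
    w = substitution_contributions(p, sigs)
    b = burden_proportions(exposures, w, sigs, mode=burden_mode)
    if b is None:
        return None
    unreachable = bool(w[lab].isna().all())
    if unreachable:
        score = 0.0
        top, mm = None, None
    else:
        score = concordance_score(b, lab)
        top, mm = mismatch_score(w, p, lab)
    return ConcordanceResult(
        tumor_id=tumor_id,
        driver_label=f"{gene} {aa_change}",
        driver_class=lab,
        w_driver=w[lab],
        burden=b,
        concordance_score=score,
        top_signature=top,
        mismatch_score=mm,
        class_unreachable=unreachable,
    )


def concordance_table(
    exposures: pd.DataFrame,
    sigs: SignatureMatrix,
    drivers: pd.DataFrame,
    burden_mode: str = "weighted",
    codon_context_table: Optional[Mapping] = None,
) -> pd.DataFrame:
    """Concordance/mismatch scores for a cohort.

    ``exposures``: one row per tumor, one column per signature (counts).
    ``drivers``: columns tumor_id, gene, aa_change and optionally
    ``substitution_class`` (used verbatim when present). Returns one row per
    analyzable tumor with per-signature ``w_`` columns appended.
    """
    required = {"tumor_id", "gene", "aa_change"}
    if not required <= set(drivers.columns):
        raise ValueError(f"drivers table needs columns {sorted(required)}")
    rows = []
    for rec in drivers.itertuples(index=False):
        tid = rec.tumor_id
        if tid not in exposures.index:
            logger.warning("tumor %s has no exposure row; skipped", tid)
            continue
        pre_class = getattr(rec, "substitution_class", None)
        if not isinstance(pre_class, str) or not pre_class:
            pre_class = None
        res = analyze_tumor(
            tid,
            exposures.loc[tid],
            sigs,
            rec.gene,
            rec.aa_change,
            burden_mode=burden_mode,
            codon_context_table=codon_context_table,
            driver_class=pre_class,
        )
        if res is None:
            continue
        row = {
            "tumor_id": res.tumor_id,
            "driver": res.driver_label,
            "driver_class": res.driver_class,
            "concordance_score": res.concordance_score,
            "top_signature": res.top_signature,
            "mismatch_score": res.mismatch_score,
            "class_unreachable": res.class_unreachable,
        }
        for k, v in res.w_driver.items():
            row[f"w_{k}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
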