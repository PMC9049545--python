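"""Mutagenic-optimality scoring of substitution classes and driver candidates.

A mutagen's propensity to produce a given SBS96 class is summarized by three
scores derived from MDS mean-frequency spectra of treated (e.g. urethane) and
vehicle-control (PBS) tissue:

* ``pbs_score``   — control mean frequency x 1e6 (the background process);
* ``delta_score`` — (treated mean - control mean) x 1e6, the vehicle-
  normalized carcinogen signal, negatives preserved;
* ``ratio_score`` — delta_score / pbs_score, with an epsilon guard on the
  denominator.

Candidate driver mutations are then placed on the delta-vs-background plane:
a candidate whose class has delta_score > pbs_score is called
``carcinogen-concordant`` (it tracks the carcinogen's spectrum), otherwise
``background-concordant``. The identity line is a configurable convention,
not a statistical test.
"""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

import pandas as pd

from .spectrum import (
    SBS96_LABELS,
    MutationSpectrum,
    SubstitutionClass,
)

logger = logging.getLogger("mutopt")

#: Scores are reported on a per-million scale.
SCALE = 1e6

#: Default denominator guard for ratio_score, on the x1e6 scale.
RATIO_EPSILON = 1e-3


def _as_label(cls: SubstitutionClass | str) -> str:
    lab = cls.label if isinstance(cls, SubstitutionClass) else str(cls)
    if lab not in SBS96_LABELS:
        raise KeyError(f"unknown substitution class {lab!r}")
    return lab


def _require_mean_frequency(spectrum: MutationSpectrum, name: str) -> None:
    if spectrum.kind != "mean_frequency":
        raise ValueError(
            f"{name} spectrum must be kind 'mean_frequency', got {spectrum.kind!r}"
        )


def pbs_optimality(
    pbs_spectrum: MutationSpectrum, cls: SubstitutionClass | str
) -> float:
    """Background (vehicle-control) optimality: mean frequency x 1e6."""
    _require_mean_frequency(pbs_spectrum, "PBS")
    return pbs_spectrum[_as_label(cls)] * SCALE


def delta_optimality(
    treated_spectrum: MutationSpectrum,
    pbs_spectrum: MutationSpectrum,
    cls: SubstitutionClass | str,
) -> float:
    """Vehicle-normalized optimality: (treated - control) x 1e6, sign kept."""
    _require_mean_frequency(treated_spectrum, "treated")
    _require_mean_frequency(pbs_spectrum, "PBS")
    lab = _as_label(cls)
    return (treated_spectrum[lab] - pbs_spectrum[lab]) * SCALE


def ratio_optimality(
    delta_score: float, pbs_score: float, epsilon: float = RATIO_EPSILON
) -> float:
    """delta_score / pbs_score with an epsilon floor on the denominator."""
    if pbs_score < epsilon:
        warnings.warn(
            f"pbs_score {pbs_score:g} below epsilon {epsilon:g}; "
            "ratio uses the epsilon floor"
        )
        return delta_score / epsilon
    return delta_score / pbs_score


def build_optimality_table(
    treated_spectrum: MutationSpectrum,
    pbs_spectrum: MutationSpectrum,
    epsilon: float = RATIO_EPSILON,
) -> pd.DataFrame:
    """Score all 96 classes; rows in SBS96 order.

    Columns: ``pbs_score``, ``delta_score``, ``ratio_score``.
    """
    _require_mean_frequency(treated_spectrum, "treated")
    _require_mean_frequency(pbs_spectrum, "PBS")
    pbs = pbs_spectrum.values * SCALE
    delta = (treated_spectrum.values - pbs_spectrum.values) * SCALE
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ratio = pd.Series(
            [ratio_optimality(d, p, epsilon) for d, p in zip(delta, pbs)],
            index=list(SBS96_LABELS),
        )
    n_floored = int((pbs < epsilon).sum())
    if n_floored:
        logger.info("ratio_score epsilon floor applied to %d classes", n_floored)
    return pd.DataFrame(
        {"pbs_score": pbs.values, "delta_score": delta.values,
         "ratio_score": ratio.values},
        index=list(SBS96_LABELS),
    )


CARCINOGEN_CONCORDANT = "carcinogen-concordant"
BACKGROUND_CONCORDANT = "background-concordant"


def concordance_call(
    delta_score: float, pbs_score: float, rule: str = "delta_gt_pbs"
) -> str:
    """Classify a scored class against the identity line (configurable)."""
    if rule != "delta_gt_pbs":
        raise ValueError(f"unknown concordance rule {rule!r}")
    return CARCINOGEN_CONCORDANT if delta_score > pbs_score else BACKGROUND_CONCORDANT


def score_candidates(
    candidates: pd.DataFrame | Sequence[dict],
    table: pd.DataFrame,
    rule: str = "delta_gt_pbs",
) -> pd.DataFrame:
    """Annotate driver candidates with optimality scores and a concordance call.

    ``candidates`` needs a ``substitution_class`` column (SBS96 labels);
    ``table`` comes from :func:`build_optimality_table` and must cover all 96
    classes. Returns a copy with ``pbs_score``, ``delta_score``,
    ``ratio_score`` and ``concordance_call`` columns appended.
    """
    df = pd.DataFrame(candidates).copy()
    if "substitution_class" not in df.columns:
        raise ValueError("candidates need a 'substitution_class' column")
    missing = set(SBS96_LABELS) - set(table.index)
    if missing:
        raise ValueError(
            f"optimality table is incomplete; {len(missing)} classes missing"
        )
    unknown = set(df["substitution_class"]) - set(table.index)
    if unknown:
        raise KeyError(f"candidate classes absent from table: {sorted(unknown)!r}")
    scores = table.loc[df["substitution_class"]]
    df["pbs_score"] = scores["pbs_score"].values
    df["delta_score"] = scores["delta_score"].values
    df["ratio_score"] = scores["ratio_score"].values
    df["concordance_call"] = [
        concordance_call(d, p, rule)
        for d, p in zip(df["delta_score"], df["pbs_score"])
    ]
    return df
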