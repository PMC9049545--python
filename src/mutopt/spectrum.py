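"""Trinucleotide-context (SBS96) substitution classification and mutation spectra.

Single-base substitutions are annotated with their immediate 5' and 3'
neighbours and collapsed onto the pyrimidine strand, giving 6 substitution
types x 16 flank pairs = 96 classes (COSMIC SBS96 convention, labels like
``A[C>T]G``).

Two kinds of spectra are built over these classes:

* **mean-frequency spectra** from maximum-depth-sequencing (MDS) style
  per-site mutant-read frequency tables, averaging the frequency of every
  (animal, position, alt) observation assigned to a class — the readout for
  mutagen exposure experiments on defined amplicons;
* **per-tumor-proportion spectra** from whole-exome SNV catalogs, where each
  tumor's class counts are normalized to proportions first and the spectrum
  is the unweighted mean of the per-tumor vectors.

MDS tables carry substitutions as read on the *sequenced* strand. Two
technical filters operate on that strand representation, before any
pyrimidine canonicalization: sequenced-strand C>T / G>T calls (a known
single-strand artifact of the assay) are removed, as are sites whose mutant
frequency exceeds an outlier ceiling (default 2e-5).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("mutopt")

BASES = ("A", "C", "G", "T")
PYRIMIDINES = ("C", "T")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: The six pyrimidine-centered substitution types, in COSMIC block order.
SUBSTITUTION_TYPES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")


def _revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


class InvalidSubstitutionError(ValueError):
    """Raised for non-ACGT bases or alt == ref."""


@dataclass(frozen=True, order=True)
class SubstitutionClass:
    """One of the 96 pyrimidine-centered trinucleotide substitution classes.

    Fields are the 5' flank, the (pyrimidine) reference base, the alternate
    base and the 3' flank, all on the strand where the mutated base is C or T.
    """

    five_prime: str
    ref: str
    alt: str
    three_prime: str

    def __post_init__(self) -> None:
        for b in (self.five_prime, self.ref, self.alt, self.three_prime):
            if b not in BASES:
                raise InvalidSubstitutionError(f"non-ACGT base {b!r}")
        if self.ref not in PYRIMIDINES:
            raise InvalidSubstitutionError(
                f"reference base must be a pyrimidine, got {self.ref!r}"
            )
        if self.alt == self.ref:
            raise InvalidSubstitutionError("alt base equals reference base")

    @property
    def label(self) -> str:
        return f"{self.five_prime}[{self.ref}>{self.alt}]{self.three_prime}"

    @property
    def substitution_type(self) -> str:
        return f"{self.ref}>{self.alt}"

    @classmethod
    def from_label(cls, label: str) -> "SubstitutionClass":
        # "A[C>T]G": positions 0,2,4,6 carry the bases
        if len(label) != 7 or label[1] != "[" or label[3] != ">" or label[5] != "]":
            raise InvalidSubstitutionError(f"malformed class label {label!r}")
        return cls(label[0], label[2], label[4], label[6])

    def __str__(self) -> str:
        return self.label


#: All 96 classes in fixed COSMIC SBS96 row order: substitution-type major
#: (C>A, C>G, C>T, T>A, T>C, T>G), then 5' flank, then 3' flank (A,C,G,T).
SBS96_CLASSES: tuple[SubstitutionClass, ...] = tuple(
    SubstitutionClass(f5, sub[0], sub[2], f3)
    for sub in SUBSTITUTION_TYPES
    for f5 in BASES
    for f3 in BASES
)

SBS96_LABELS: tuple[str, ...] = tuple(c.label for c in SBS96_CLASSES)

_LABEL_INDEX = {lab: i for i, lab in enumerate(SBS96_LABELS)}


def classify_substitution(tri_context: str, alt: str) -> SubstitutionClass:
    """Map a substitution given in any strand orientation to its SBS96 class.

    ``tri_context`` is the 3-mer centered on the mutated base, read 5'->3' on
    the strand the substitution was observed on; ``alt`` is the observed
    alternate base on that same strand. If the central base is a purine the
    substitution is reverse-complemented onto the pyrimidine strand.
    """
    tri = str(tri_context).upper()
    alt = str(alt).upper()
    if len(tri) != 3:
        raise InvalidSubstitutionError(f"tri_context must be a 3-mer, got {tri!r}")
    for b in (*tri, alt):
        if b not in BASES:
            raise InvalidSubstitutionError(f"non-ACGT base {b!r} in {tri!r}>{alt!r}")
    ref = tri[1]
    if alt == ref:
        raise InvalidSubstitutionError(f"alt equals reference base {ref!r}")
    if ref in PYRIMIDINES:
        return SubstitutionClass(tri[0], ref, alt, tri[2])
    rc = _revcomp(tri)
    return SubstitutionClass(rc[0], rc[1], COMPLEMENT[alt], rc[2])


@dataclass(frozen=True)
class MDSSiteObservation:
    """One per-site, per-substitution mutant-read frequency from an MDS assay.

    ``ref``/``alt`` and ``tri_context`` are as read on the sequenced strand
    (canonicalization is deferred until after artifact filtering);
    ``frequency`` is mutant reads / total reads at the site.
    """

    animal_id: str
    arm: str
    amplicon: str
    position: int
    ref: str
    alt: str
    tri_context: str
    frequency: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.frequency <= 1.0:
            raise ValueError(f"frequency {self.frequency} outside [0, 1]")
        if self.tri_context[1] != self.ref:
            raise ValueError(
                f"tri_context {self.tri_context} center != ref {self.ref}"
            )

    @property
    def substitution_class(self) -> SubstitutionClass:
        return classify_substitution(self.tri_context, self.alt)


SPECTRUM_KINDS = ("mean_frequency", "per_tumor_proportion_mean", "delta")


@dataclass
class MutationSpectrum:
    """A 96-vector over substitution classes with provenance metadata.

    ``values`` is a pandas Series indexed by the fixed SBS96 label order;
    ``kind`` records how it was built (``mean_frequency`` for MDS-style
    averages, ``per_tumor_proportion_mean`` for WES-style proportion means,
    ``delta`` for differences); ``n_units`` counts contributing tumors or
    observations.
    """

    values: pd.Series
    kind: str
    arm_label: str = ""
    n_units: int = 0

    def __post_init__(self) -> None:
        if self.kind not in SPECTRUM_KINDS:
            raise ValueError(f"unknown spectrum kind {self.kind!r}")
        vals = pd.Series(self.values, dtype=float)
        vals = vals.reindex(SBS96_LABELS, fill_value=0.0)
        extra = set(pd.Series(self.values).index) - set(SBS96_LABELS)
        if extra:
            raise ValueError(f"unknown class labels in spectrum: {sorted(extra)!r}")
        object.__setattr__(self, "values", vals)
        if self.kind == "mean_frequency" and (vals < 0).any():
            raise ValueError("mean_frequency spectrum contains negative values")
        if self.kind == "per_tumor_proportion_mean" and self.n_units > 0:
            total = float(vals.sum())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"proportion spectrum sums to {total}, not 1")

    def __getitem__(self, cls: SubstitutionClass | str) -> float:
        key = cls.label if isinstance(cls, SubstitutionClass) else cls
        return float(self.values[key])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"class": SBS96_LABELS, "value": self.values.values})


def filter_mds_artifacts(
    observations: Sequence[MDSSiteObservation],
    outlier_threshold: float = 2e-5,
) -> list[MDSSiteObservation]:
    """Remove assay artifacts from sequenced-strand MDS observations.

    Drops (i) observations whose sequenced-strand substitution is C>T or G>T —
    a single-strand chemistry artifact of the assay not mirrored on the
    complementary strand — and (ii) observations with frequency above
    ``outlier_threshold`` (default 2e-5). Operates strictly on the
    sequenced-strand identity, before pyrimidine canonicalization.
    """
    kept = []
    for obs in observations:
        if (obs.ref, obs.alt) in (("C", "T"), ("G", "T")):
            continue
        if obs.frequency > outlier_threshold:
            continue
        kept.append(obs)
    return kept


def build_mds_spectrum(
    observations: Sequence[MDSSiteObservation],
    arm: str,
    per_animal_first: bool = False,
    nonzero_only: bool = False,
) -> MutationSpectrum:
    """Average per-site mutant frequencies into a 96-class mean-frequency spectrum.

    Each (animal, position, alt) observation contributes its frequency to the
    mean of its canonicalized class; classes with no observations are 0. By
    default every observation has equal weight ("averaged across all
    nucleotide positions in all mice" read literally, zero-frequency assayed
    sites included); ``per_animal_first=True`` averages within each animal
    before averaging across animals, and ``nonzero_only=True`` drops
    zero-frequency observations before averaging.
    """
    obs = [o for o in observations if o.arm == arm]
    if len(obs) != len(observations):
        raise ValueError(
            f"{len(observations) - len(obs)} observations are not from arm {arm!r}"
        )
    if nonzero_only:
        obs = [o for o in obs if o.frequency > 0]
    if not obs:
        warnings.warn(f"no MDS observations for arm {arm!r}; all-zero spectrum")
        return MutationSpectrum(
            pd.Series(0.0, index=list(SBS96_LABELS)), "mean_frequency", arm, 0
        )
    labels = [o.substitution_class.label for o in obs]
    freqs = [o.frequency for o in obs]
    if per_animal_first:
        df = pd.DataFrame(
            {"animal": [o.animal_id for o in obs], "label": labels, "f": freqs}
        )
        per_animal = (
            df.groupby(["animal", "label"])["f"].mean().unstack(fill_value=np.nan)
        )
        # across-animal mean over animals that assayed the class at all
        means = per_animal.mean(axis=0, skipna=True)
    else:
        means = pd.Series(freqs, dtype=float).groupby(pd.Series(labels)).mean()
    values = means.reindex(SBS96_LABELS, fill_value=0.0).fillna(0.0)
    return MutationSpectrum(values, "mean_frequency", arm, n_units=len(obs))


def build_wes_spectrum(
    snvs: Iterable[tuple[str, SubstitutionClass | str]],
    arm_label: str = "WES",
) -> MutationSpectrum:
    """Mean of per-tumor class-proportion vectors from a tumor SNV catalog.

    Per tumor, SBS96 class counts are normalized to proportions; the spectrum
    is the unweighted mean over tumors (so a tumor with 3 SNVs counts as much
    as one with 300). Tumors with zero SNVs simply do not appear in the input.
    """
    records = [
        (tid, c.label if isinstance(c, SubstitutionClass) else str(c))
        for tid, c in snvs
    ]
    if not records:
        raise ValueError("no SNVs supplied; cannot normalize an empty catalog")
    for _, lab in records:
        if lab not in _LABEL_INDEX:
            raise InvalidSubstitutionError(f"unknown class label {lab!r}")
    df = pd.DataFrame(records, columns=["tumor", "label"])
    counts = df.groupby(["tumor", "label"]).size().unstack(fill_value=0)
    counts = counts.reindex(columns=SBS96_LABELS, fill_value=0)
    props = counts.div(counts.sum(axis=1), axis=0)
    mean = props.mean(axis=0)
    return MutationSpectrum(
        mean, "per_tumor_proportion_mean", arm_label, n_units=counts.shape[0]
    )
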