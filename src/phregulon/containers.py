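"""Core in-memory containers shared across the pipeline.

The pipeline moves a genes x samples signal table through three scales:

* ``raw`` — background-subtracted fluorescence, arbitrary units, >= 0 after
  flooring;
* ``log10`` — log10 signal after per-sample anchoring to the reference
  spike-in;
* ``normalized_concentration`` — log10 relative concentration obtained by
  piecewise-linear interpolation through the ten spike-in knots.

Ten exogenous spike-in transcripts of known log10 relative concentration ride
along as flagged rows and calibrate each sample; the anchor spike
(``E1A_r60_a20`` at log10 concentration 3.83 in the assay this models) pins
the per-sample shift.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

VALID_STRAINS = ("wt", "dpacC", "pacCc")
VALID_PH = (4, 8)
SCALES = ("raw", "log10", "normalized_concentration")

#: IUPAC nucleotide one-letter codes -> set of concrete bases matched.
IUPAC_CODES: Mapping[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"), "R": frozenset("AG"), "Y": frozenset("CT"),
    "S": frozenset("CG"), "W": frozenset("AT"), "K": frozenset("GT"),
    "M": frozenset("AC"), "B": frozenset("CGT"), "D": frozenset("AGT"),
    "H": frozenset("ACT"), "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

DEFAULT_ANCHOR_ID = "E1A_r60_a20"
DEFAULT_ANCHOR_LOG10_CONC = 3.83

#: Standard KOG functional classes (one-letter code -> description).
KOG_CLASSES: Mapping[str, str] = {
    "A": "RNA processing and modification",
    "B": "Chromatin structure and dynamics",
    "C": "Energy production and conversion",
    "D": "Cell cycle control, cell division, chromosome partitioning",
    "E": "Amino acid transport and metabolism",
    "F": "Nucleotide transport and metabolism",
    "G": "Carbohydrate transport and metabolism",
    "H": "Coenzyme transport and metabolism",
    "I": "Lipid transport and metabolism",
    "J": "Translation, ribosomal structure and biogenesis",
    "K": "Transcription",
    "L": "Replication, recombination and repair",
    "M": "Cell wall/membrane/envelope biogenesis",
    "N": "Cell motility",
    "O": "Posttranslational modification, protein turnover, chaperones",
    "P": "Inorganic ion transport and metabolism",
    "Q": "Secondary metabolites biosynthesis, transport and catabolism",
    "R": "General function prediction only",
    "S": "Function unknown",
    "T": "Signal transduction mechanisms",
    "U": "Intracellular trafficking, secretion, and vesicular transport",
    "V": "Defense mechanisms",
    "W": "Extracellular structures",
    "Y": "Nuclear structure",
    "Z": "Cytoskeleton",
}


class PhregulonError(Exception):
    """Base class for all package errors."""


class ValidationError(PhregulonError):
    """Malformed or inconsistent input data."""


@dataclass
class ExpressionMatrix:
    """Genes x samples signal table with spike-in row flags.

    Parameters
    ----------
    values
        DataFrame indexed by gene id, columns are sample ids.
    spike_flags
        Boolean Series over the same gene index; True marks spike-in rows.
    scale
        One of ``raw``, ``log10``, ``normalized_concentration``.
    """

    values: pd.DataFrame
    spike_flags: pd.Series
    scale: str = "raw"

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValidationError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        idx = self.values.index
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dups}")
        cols = self.values.columns
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        self.spike_flags = self.spike_flags.reindex(idx)
        if self.spike_flags.isna().any():
            raise ValidationError("spike_flags must cover every gene row")
        self.spike_flags = self.spike_flags.astype(bool)
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        if not np.isfinite(arr).all():
            raise ValidationError("expression values must be finite (no NaN/inf)")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def spike_ids(self) -> pd.Index:
        return self.values.index[self.spike_flags.to_numpy()]

    def gene_values(self) -> pd.DataFrame:
        """Non-spike rows only (the biological genes)."""
        return self.values.loc[~self.spike_flags]

    def with_values(self, values: pd.DataFrame, scale: str) -> "ExpressionMatrix":
        return ExpressionMatrix(values=values, spike_flags=self.spike_flags.copy(), scale=scale)


@dataclass
class SampleMetadata:
    """Sample -> (strain, pH, replicate) design table."""

    table: pd.DataFrame  # index: sample id; columns: strain, pH, replicate

    def __post_init__(self) -> None:
        t = self.table
        missing = {"strain", "pH", "replicate"} - set(t.columns)
        if missing:
            raise ValidationError(f"sample sheet missing columns: {sorted(missing)}")
        if t.index.has_duplicates:
            dups = t.index[t.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids in sheet: {dups}")
        bad = set(t["strain"]) - set(VALID_STRAINS)
        if bad:
            raise ValidationError(f"unknown strain labels {sorted(bad)}; allowed: {VALID_STRAINS}")
        self.table["pH"] = t["pH"].astype(int)
        bad_ph = set(self.table["pH"]) - set(VALID_PH)
        if bad_ph:
            raise ValidationError(f"unsupported pH values {sorted(bad_ph)}; only {VALID_PH} are modeled")
        reps = t["replicate"].astype(int)
        if (reps < 1).any():
            raise ValidationError("replicate numbers must be positive integers")
        self.table["replicate"] = reps

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    def condition_of(self, sample: str) -> str:
        row = self.table.loc[sample]
        return condition_label(row["strain"], int(row["pH"]))

    def conditions(self) -> pd.Series:
        """Per-sample condition label, e.g. ``wt_pH8``."""
        return pd.Series(
            [condition_label(s, p) for s, p in zip(self.table["strain"], self.table["pH"])],
            index=self.table.index,
            name="condition",
        )

    def condition_samples(self) -> dict[str, list[str]]:
        """Condition label -> list of member sample ids (insertion order)."""
        out: dict[str, list[str]] = {}
        for sample, cond in self.conditions().items():
            out.setdefault(cond, []).append(sample)
        return out

    def check_matches(self, matrix: ExpressionMatrix, min_replicates: int = 2) -> None:
        """Validate the sheet against a matrix: coverage and replication."""
        absent = [s for s in matrix.sample_ids if s not in self.table.index]
        if absent:
            raise ValidationError(f"samples present in matrix but absent from sheet: {absent}")
        for cond, members in self.condition_samples().items():
            if len(members) < min_replicates:
                raise ValidationError(
                    f"condition {cond} has {len(members)} replicate(s); "
                    f">= {min_replicates} required for variance estimation"
                )


def condition_label(strain: str, ph: int) -> str:
    return f"{strain}_pH{ph}"


@dataclass
class SpikeSet:
    """Spike-in ids with known log10 relative concentrations and an anchor."""

    log10_concentration: pd.Series  # index: spike id
    anchor_id: str = DEFAULT_ANCHOR_ID

    def __post_init__(self) -> None:
        conc = self.log10_concentration.astype(float)
        if conc.index.has_duplicates:
            raise ValidationError("duplicate spike ids")
        if self.anchor_id not in conc.index:
            raise ValidationError(f"anchor spike {self.anchor_id!r} not in spike set")
        vals = np.sort(conc.to_numpy())
        if len(vals) >= 2 and np.any(np.diff(vals) <= 0):
            raise ValidationError("spike log10 concentrations must be distinct")
        self.log10_concentration = conc

    def __len__(self) -> int:
        return len(self.log10_concentration)

    @property
    def spike_ids(self) -> pd.Index:
        return self.log10_concentration.index

    @classmethod
    def default(cls) -> "SpikeSet":
        """Ten equally spaced log10 concentrations spanning four decades,
        with the anchor fixed at 3.83 as the top knot."""
        conc = np.linspace(DEFAULT_ANCHOR_LOG10_CONC - 4.0, DEFAULT_ANCHOR_LOG10_CONC, 10)
        ids = [f"spike_{i + 1:02d}" for i in range(9)] + [DEFAULT_ANCHOR_ID]
        return cls(pd.Series(conc, index=ids), anchor_id=DEFAULT_ANCHOR_ID)


@dataclass
class PromoterSet:
    """Gene id -> upstream sequence (coding strand, 5'->3', nominally 1 kb)."""

    sequences: dict[str, str]
    lengths: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        valid = set(IUPAC_CODES)
        for gene, seq in self.sequences.items():
            if not seq:
                raise ValidationError(f"empty promoter sequence for {gene!r}")
            bad = set(seq) - valid
            if bad:
                raise ValidationError(f"non-IUPAC characters {sorted(bad)} in promoter of {gene!r}")
        self.lengths = pd.Series({g: len(s) for g, s in self.sequences.items()}, dtype=int)

    def __len__(self) -> int:
        return len(self.sequences)

    def __contains__(self, gene: str) -> bool:
        return gene in self.sequences

    @property
    def gene_ids(self) -> list[str]:
        return list(self.sequences)


@dataclass
class KogAnnotation:
    """Gene id -> set of KOG class labels (genes may be unannotated)."""

    classes: dict[str, frozenset[str]]
    vocabulary: frozenset[str] = frozenset(KOG_CLASSES)

    def __post_init__(self) -> None:
        for gene, labels in self.classes.items():
            bad = set(labels) - self.vocabulary
            if bad:
                raise ValidationError(
                    f"gene {gene!r} carries classes {sorted(bad)} outside the declared vocabulary"
                )
            self.classes[gene] = frozenset(labels)

    def annotated_genes(self, universe: Iterable[str] | None = None) -> list[str]:
        genes = self.classes if universe is None else [g for g in universe if g in self.classes]
        return [g for g in genes if self.classes[g]]

    def class_members(self, universe: Iterable[str] | None = None) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for g in self.annotated_genes(universe):
            for c in self.classes[g]:
                out.setdefault(c, set()).add(g)
        return out
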