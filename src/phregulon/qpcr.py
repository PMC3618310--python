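"""qPCR validation toolkit: standard-curve efficiency and relative
quantification against reference genes.

Amplification efficiency comes from a serial-dilution standard curve: with
Ct regressed on log10 input quantity, efficiency% = (10^(-1/slope) - 1) * 100
(a perfect doubling chemistry gives slope -1/log10(2) = -3.3219 and 100%).

Relative quantity uses the comparative-Ct method with multiple reference
genes: dCt = Ct_gene - mean(Ct_refs) per sample, ddCt relative to a
calibrator sample, RQ = E^(-ddCt) with E = 2 by default or the
efficiency-corrected base. Replicate Cts are averaged before dCt; their
scatter is propagated to an RQ interval by the delta method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ValidationError


@dataclass
class StandardCurve:
    """Least-squares fit of Ct on log10 input quantity."""

    log10_quantity: np.ndarray
    ct: np.ndarray
    slope: float
    intercept: float

    @classmethod
    def fit(cls, log10_quantity, ct) -> "StandardCurve":
        x = np.asarray(log10_quantity, dtype=float)
        y = np.asarray(ct, dtype=float)
        if len(x) < 3:
            raise ValidationError("standard curve needs >= 3 dilution points")
        slope, intercept = np.polyfit(x, y, 1)
        return cls(log10_quantity=x, ct=y, slope=float(slope), intercept=float(intercept))

    @property
    def valid(self) -> bool:
        return self.slope < 0

    @property
    def efficiency_percent(self) -> float:
        return primer_efficiency(self.slope)

    @property
    def efficiency_base(self) -> float:
        """Per-cycle amplification factor E (2.0 at 100% efficiency)."""
        return 1.0 + self.efficiency_percent / 100.0


def primer_efficiency(slope: float) -> float:
    """Efficiency% = (10^(-1/slope) - 1) * 100 from the standard-curve slope."""
    if slope == 0:
        raise ValidationError("standard-curve slope is zero; efficiency undefined")
    if slope > 0:
        raise ValidationError(f"slope {slope} > 0: invalid standard curve (Ct must fall with input)")
    return (10.0 ** (-1.0 / slope) - 1.0) * 100.0


@dataclass
class QpcrRun:
    """Ct measurements in long form with reference genes and a calibrator.

    ``ct_table`` columns: gene, sample, ct (one row per technical replicate).
    """

    ct_table: pd.DataFrame
    reference_genes: tuple[str, ...]
    calibrator: str

    def __post_init__(self) -> None:
        missing = {"gene", "sample", "ct"} - set(self.ct_table.columns)
        if missing:
            raise ValidationError(f"ct table missing columns: {sorted(missing)}")
        if (self.ct_table["ct"] <= 0).any():
            raise ValidationError("all Ct values must be > 0")
        samples = set(self.ct_table["sample"])
        if self.calibrator not in samples:
            raise ValidationError(f"calibrator sample {self.calibrator!r} has no Ct data")
        for ref in self.reference_genes:
            ref_samples = set(self.ct_table.loc[self.ct_table["gene"] == ref, "sample"])
            absent = samples - ref_samples
            if absent:
                raise ValidationError(
                    f"reference gene {ref!r} missing Ct in sample(s): {sorted(absent)}"
                )

    def _mean_sem2(self, gene: str, sample: str) -> tuple[float, float]:
        cts = self.ct_table.loc[
            (self.ct_table["gene"] == gene) & (self.ct_table["sample"] == sample), "ct"
        ].to_numpy(dtype=float)
        if cts.size == 0:
            raise ValidationError(f"no Ct for gene {gene!r} in sample {sample!r}")
        sem2 = float(cts.var(ddof=1) / cts.size) if cts.size > 1 else 0.0
        return float(cts.mean()), sem2

    def delta_ct(self, gene: str, sample: str) -> tuple[float, float]:
        """dCt = mean Ct_gene - mean of reference mean Cts; returns (dCt, var)."""
        g_mean, g_var = self._mean_sem2(gene, sample)
        ref_means, ref_vars = [], []
        for ref in self.reference_genes:
            m, v = self._mean_sem2(ref, sample)
            ref_means.append(m)
            ref_vars.append(v)
        n_ref = len(ref_means)
        dct = g_mean - float(np.mean(ref_means))
        var = g_var + float(np.sum(ref_vars)) / n_ref**2
        return dct, var


def relative_quantity(
    run: QpcrRun,
    gene: str,
    sample: str,
    efficiency_base: float = 2.0,
) -> dict[str, float]:
    """RQ of a gene in a sample relative to the calibrator.

    Returns RQ plus a delta-method SD and the underlying dCt/ddCt. RQ of the
    calibrator itself is exactly 1.
    """
    if efficiency_base <= 1.0:
        raise ValidationError("efficiency base must exceed 1 (no amplification otherwise)")
    dct_s, var_s = run.delta_ct(gene, sample)
    dct_c, var_c = run.delta_ct(gene, run.calibrator)
    if sample == run.calibrator:
        ddct, var = 0.0, 0.0
    else:
        ddct = dct_s - dct_c
        var = var_s + var_c
    rq = efficiency_base ** (-ddct)
    rq_sd = rq * math.log(efficiency_base) * math.sqrt(var)
    return {"rq": rq, "rq_sd": rq_sd, "ddct": ddct, "dct": dct_s}


def rq_table(run: QpcrRun, genes: list[str] | None = None, efficiency_base: float = 2.0) -> pd.DataFrame:
    """RQ for every (target gene, sample) pair in the run."""
    all_genes = [g for g in run.ct_table["gene"].unique() if g not in run.reference_genes]
    genes = genes or all_genes
    samples = list(run.ct_table["sample"].unique())
    rows = []
    for gene in genes:
        for sample in samples:
            res = relative_quantity(run, gene, sample, efficiency_base)
            rows.append({"gene": gene, "sample": sample, **res})
    return pd.DataFrame(rows)
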