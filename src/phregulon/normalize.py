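"""Three-step spike-in normalization and replicate averaging.

Single-channel array signals are made comparable across samples by

1. **anchoring** — log10 signals are shifted per sample so the anchor
   spike-in (known log10 relative concentration 3.83) takes the same value,
   the cross-sample mean, in every sample;
2. **interpolation to concentration** — each sample's ten spike-in
   (log signal -> log concentration) pairs define a piecewise-linear map
   applied to every gene; values beyond the outermost knots are extrapolated
   with the terminal segment's slope and flagged in the audit;
3. **percentile scaling** — a per-sample additive shift (log scale) equalizes
   the 75th percentile of the non-spike genes across samples.

Replicates are then averaged per (strain, pH) condition on the normalized
log10 scale. Spike rows never enter the percentile or any downstream
statistic.

The distortion family this chain can undo exactly is affine in log10 space:
log signal = slope * log concentration + offset per sample. Anchoring removes
the offset differences, interpolation inverts the slope, and percentile
scaling removes any residual per-sample constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    ExpressionMatrix,
    SampleMetadata,
    SpikeSet,
    ValidationError,
)


@dataclass
class NormalizationAudit:
    """Per-sample record of what each normalization step did."""

    anchor_shift: pd.Series | None = None
    knots: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    extrapolated_low: pd.Series | None = None
    extrapolated_high: pd.Series | None = None
    percentile_before: pd.Series | None = None
    percentile_after: pd.Series | None = None

    def as_frame(self) -> pd.DataFrame:
        cols = {}
        for name in ("anchor_shift", "extrapolated_low", "extrapolated_high",
                     "percentile_before", "percentile_after"):
            val = getattr(self, name)
            if val is not None:
                cols[name] = val
        return pd.DataFrame(cols)


def anchor_to_spike(
    m: ExpressionMatrix,
    spikes: SpikeSet,
    floor_eps: float = 1.0,
    audit: NormalizationAudit | None = None,
) -> ExpressionMatrix:
    """log10-transform and shift each sample so the anchor row is constant.

    Raw signals <= 0 (possible after background subtraction) are floored to
    ``floor_eps`` signal units before taking log10; flooring preserves rank.
    The per-sample shift equalizes the anchor spike at its cross-sample mean.
    """
    if m.scale != "raw":
        raise ValidationError(f"anchor_to_spike expects a raw-scale matrix, got {m.scale!r}")
    anchor = spikes.anchor_id
    if anchor not in m.values.index:
        raise ValidationError(f"anchor spike {anchor!r} missing from matrix")
    raw_anchor = m.values.loc[anchor]
    if (raw_anchor <= 0).any():
        bad = list(raw_anchor.index[raw_anchor <= 0])
        raise ValidationError(f"anchor signal <= 0 in sample(s): {bad}")
    log_values = np.log10(m.values.clip(lower=floor_eps))
    anchor_log = log_values.loc[anchor]
    shift = anchor_log.mean() - anchor_log
    out = log_values.add(shift, axis="columns")
    if audit is not None:
        audit.anchor_shift = shift.rename("anchor_shift")
    return m.with_values(out, scale="log10")


def _collapse_tied_knots(signals: np.ndarray, concs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sort knots by signal; average signal-tied knots into one."""
    order = np.argsort(signals, kind="stable")
    s, c = signals[order], concs[order]
    xs, ys = [], []
    i = 0
    while i < len(s):
        j = i
        while j + 1 < len(s) and s[j + 1] == s[i]:
            j += 1
        xs.append(s[i : j + 1].mean())
        ys.append(c[i : j + 1].mean())
        i = j + 1
    return np.asarray(xs), np.asarray(ys)


def _piecewise_linear(x: np.ndarray, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    y = np.interp(x, xs, ys)
    lo, hi = x < xs[0], x > xs[-1]
    if lo.any():
        slope = (ys[1] - ys[0]) / (xs[1] - xs[0])
        y[lo] = ys[0] + (x[lo] - xs[0]) * slope
    if hi.any():
        slope = (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])
        y[hi] = ys[-1] + (x[hi] - xs[-1]) * slope
    return y


def interpolate_to_concentration(
    m: ExpressionMatrix,
    spikes: SpikeSet,
    audit: NormalizationAudit | None = None,
) -> ExpressionMatrix:
    """Map anchored log10 signals to log10 concentrations per sample.

    Each sample's spike rows give (observed log signal, known log
    concentration) knots; genes are piecewise-linearly interpolated through
    them, with terminal-slope extrapolation outside the knot range.
    """
    if m.scale != "log10":
        raise ValidationError(f"interpolate_to_concentration expects log10 scale, got {m.scale!r}")
    missing = [s for s in spikes.spike_ids if s not in m.values.index]
    if missing:
        raise ValidationError(f"spike rows missing from matrix: {missing}")
    spike_signals = m.values.loc[spikes.spike_ids]
    concs = spikes.log10_concentration.to_numpy()
    out = pd.DataFrame(index=m.values.index, columns=m.values.columns, dtype=float)
    n_low = pd.Series(0, index=m.values.columns, dtype=int)
    n_high = pd.Series(0, index=m.values.columns, dtype=int)
    for sample in m.values.columns:
        xs, ys = _collapse_tied_knots(spike_signals[sample].to_numpy(), concs)
        if len(xs) < 2:
            raise ValidationError(
                f"sample {sample!r}: fewer than 2 distinct spike signals; cannot interpolate"
            )
        x = m.values[sample].to_numpy()
        out[sample] = _piecewise_linear(x, xs, ys)
        n_low[sample] = int((x < xs[0]).sum())
        n_high[sample] = int((x > xs[-1]).sum())
        if audit is not None:
            audit.knots[sample] = (xs, ys)
    if audit is not None:
        audit.extrapolated_low = n_low.rename("extrapolated_low")
        audit.extrapolated_high = n_high.rename("extrapolated_high")
    return m.with_values(out, scale="normalized_concentration")


def scale_to_percentile(
    m: ExpressionMatrix,
    q: float = 0.75,
    audit: NormalizationAudit | None = None,
) -> ExpressionMatrix:
    """Shift each sample so its q-quantile of non-spike genes is the
    cross-sample mean quantile (linear-interpolation quantiles)."""
    genes = m.gene_values()
    if len(genes) < 4:
        raise ValidationError("need >= 4 non-spike genes per sample for percentile scaling")
    before = genes.quantile(q, interpolation="linear")
    if (genes.nunique() <= 1).any():
        bad = list(genes.columns[genes.nunique() <= 1])
        raise ValidationError(f"degenerate (constant) sample(s): {bad}")
    target = before.mean()
    out = m.values.add(target - before, axis="columns")
    if audit is not None:
        audit.percentile_before = before.rename("percentile_before")
        after = out.loc[~m.spike_flags].quantile(q, interpolation="linear")
        audit.percentile_after = after.rename("percentile_after")
    return m.with_values(out, scale=m.scale)


def average_replicates(m: ExpressionMatrix, meta: SampleMetadata) -> pd.DataFrame:
    """Arithmetic mean per (strain, pH) condition on the normalized log10
    scale; returns a genes x conditions DataFrame (spike rows dropped)."""
    meta.check_matches(m, min_replicates=1)
    cond_samples = meta.condition_samples()
    genes = m.gene_values()
    out = {}
    for cond, members in cond_samples.items():
        members = [s for s in members if s in genes.columns]
        if not members:
            raise ValidationError(f"condition {cond} has no samples in the matrix")
        out[cond] = genes[members].mean(axis=1)
    return pd.DataFrame(out)


def normalize_expression(
    m: ExpressionMatrix,
    spikes: SpikeSet,
    q: float = 0.75,
    floor_eps: float = 1.0,
) -> tuple[ExpressionMatrix, NormalizationAudit]:
    """Full chain: anchor -> interpolate to concentration -> percentile scale."""
    if len(spikes) != 10:
        raise ValidationError(f"spike normalization requires 10 spike-ins, got {len(spikes)}")
    present = [s for s in spikes.spike_ids if s in m.values.index]
    if len(present) != len(spikes):
        missing = sorted(set(spikes.spike_ids) - set(present))
        raise ValidationError(f"spike rows missing from matrix: {missing}")
    flagged = set(m.spike_ids)
    if flagged != set(spikes.spike_ids):
        raise ValidationError(
            "matrix spike flags disagree with the spike set: "
            f"{sorted(flagged.symmetric_difference(spikes.spike_ids))}"
        )
    audit = NormalizationAudit()
    out = anchor_to_spike(m, spikes, floor_eps=floor_eps, audit=audit)
    out = interpolate_to_concentration(out, spikes, audit=audit)
    out = scale_to_percentile(out, q=q, audit=audit)
    return out, audit
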