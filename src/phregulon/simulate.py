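"""Synthetic experiments with known ground truth.

The generator emulates the study design this package targets: two strains
(wild type and a pacC deletion mutant; the constitutively active allele can
be enabled as a third strain) x two ambient pH levels (4 and 8) x three
biological replicates, on a single-channel array measuring ~12k genes plus
ten spike-in controls of known log10 relative concentration.

The measurement model, all on the log10 scale:

    log10 signal[g, s] = scale + slope_s * true_log_conc[g, s] + offset_s + noise[g, s]

with per-sample affine distortions (slope_s, offset_s) — exactly the family
the spike-interpolation normalization can undo — and gene noise
noise ~ Normal(0, sigma_g), sigma_g^2 ~ scaled-inv-chi2(d0_true, s0_true^2),
so the empirical-Bayes variance prior downstream is well-specified and its
hyperparameters are recoverable. Spike rows pass through the same distortion
noise-free (they model low-noise exogenous controls).

Regulon archetypes plant condition effects on true_log_conc:

* ``ph_up`` / ``ph_down`` — pH response of the same sign in both strains
  (PacC-independent);
* ``pacc_up`` / ``pacc_down`` — pH response in the wild type only, so the
  gene is also differential between strains at pH 8;
* ``acid_up`` / ``acid_down`` — strain difference at pH 4 only (the
  "acid-regulated" pattern: higher/lower in the mutant at pH 4);
* ``gating_up`` / ``gating_down`` — concordant pH response in both strains,
  but the mutant's overall level is dropped (PacC gates amplitude, not
  direction);
* ``null`` — no planted effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .containers import (
    ExpressionMatrix,
    KogAnnotation,
    PromoterSet,
    SampleMetadata,
    SpikeSet,
    ValidationError,
    condition_label,
)
from .motif import MotifSpec, expand_iupac

ARCHETYPES = (
    "null",
    "ph_up",
    "ph_down",
    "pacc_up",
    "pacc_down",
    "acid_up",
    "acid_down",
    "gating_up",
    "gating_down",
)

#: Contrasts evaluated downstream, as (condition_a, condition_b) pairs;
#: fold change is a/b.
DEFAULT_CONTRASTS: Mapping[str, tuple[str, str]] = {
    "wt8_vs_wt4": ("wt_pH8", "wt_pH4"),
    "mut8_vs_mut4": ("dpacC_pH8", "dpacC_pH4"),
    "wt8_vs_mut8": ("wt_pH8", "dpacC_pH8"),
    "wt4_vs_mut4": ("wt_pH4", "dpacC_pH4"),
}


def _default_archetype_sizes() -> dict[str, int]:
    # 200 planted effects in a 2000-gene experiment, mirroring the scale of
    # the pH response observed on the real array (~650 of 12,427 genes).
    return {
        "ph_up": 40,
        "ph_down": 40,
        "pacc_up": 40,
        "pacc_down": 40,
        "acid_up": 10,
        "acid_down": 10,
        "gating_up": 10,
        "gating_down": 10,
    }


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic experiment; defaults are the study conditions."""

    n_genes: int = 2000
    strains: tuple[str, ...] = ("wt", "dpacC")
    ph_levels: tuple[int, ...] = (4, 8)
    replicates: int = 3
    baseline_mean: float = 2.0   # log10 concentration
    baseline_sd: float = 0.7
    # Global log10 signal scale: raw signal = 10^(signal_scale + distorted log
    # concentration). Places signals in realistic fluorescence units so the
    # background-subtraction floor (1 signal unit) sits below every
    # detectable transcript, as on a real scanner.
    signal_scale: float = 2.0
    slope_range: tuple[float, float] = (0.8, 1.2)
    offset_range: tuple[float, float] = (-0.5, 0.5)
    d0_true: float = 4.0         # prior df of the gene-variance distribution
    s0_true2: float = 0.02       # prior scale (log10 units squared)
    planted_log10_fc: float = 0.6
    gating_drop: float = 0.6     # log10 drop of mutant level for gating genes
    archetype_sizes: dict[str, int] = field(default_factory=_default_archetype_sizes)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ValidationError("replicates must be >= 2 for variance estimation")
        unknown = set(self.archetype_sizes) - set(ARCHETYPES)
        if unknown:
            raise ValidationError(f"unknown archetypes: {sorted(unknown)}")
        if sum(self.archetype_sizes.values()) > self.n_genes:
            raise ValidationError("archetype sizes exceed n_genes (oversubscription)")
        if self.planted_log10_fc <= 0:
            raise ValidationError("planted |log10 FC| must be > 0 for DE archetypes")


@dataclass
class GroundTruth:
    """Everything needed to score downstream calls against the simulation."""

    archetype: pd.Series                 # gene -> archetype label
    true_log10_fc: pd.DataFrame          # genes x contrasts
    sample_slope: pd.Series
    sample_offset: pd.Series
    true_log_concentration: pd.DataFrame  # genes x samples (noise-free, undistorted)
    gene_sigma2: pd.Series
    d0_true: float
    s0_true2: float

    def genes_of(self, archetype: str) -> set[str]:
        return set(self.archetype.index[self.archetype == archetype])


def _condition_effect(arch: str, strain: str, ph: int, fc: float, drop: float) -> float:
    alk = ph == 8
    mut = strain == "dpacC"
    if arch == "ph_up":
        return fc if alk else 0.0
    if arch == "ph_down":
        return -fc if alk else 0.0
    if arch == "pacc_up":
        return fc if (alk and not mut) else 0.0
    if arch == "pacc_down":
        return -fc if (alk and not mut) else 0.0
    if arch == "acid_up":
        return fc if (mut and not alk) else 0.0
    if arch == "acid_down":
        return -fc if (mut and not alk) else 0.0
    if arch == "gating_up":
        return (fc if alk else 0.0) - (drop if mut else 0.0)
    if arch == "gating_down":
        return (-fc if alk else 0.0) - (drop if mut else 0.0)
    return 0.0


def generate_expression_experiment(
    config: SyntheticConfig,
) -> tuple[ExpressionMatrix, SampleMetadata, SpikeSet, GroundTruth]:
    """Simulate a raw signal matrix with spike-ins, design sheet and truth."""
    rng = np.random.default_rng(config.seed)
    spikes = SpikeSet.default()

    gene_ids = [f"g{i + 1:05d}" for i in range(config.n_genes)]
    # Assign archetypes to a random subset of genes.
    labels = np.array(["null"] * config.n_genes, dtype=object)
    order = rng.permutation(config.n_genes)
    pos = 0
    for arch in ARCHETYPES:
        size = config.archetype_sizes.get(arch, 0)
        labels[order[pos : pos + size]] = arch
        pos += size
    archetype = pd.Series(labels, index=gene_ids, name="archetype")

    # Design: strains x pH x replicates.
    rows = []
    for strain in config.strains:
        for ph in config.ph_levels:
            for rep in range(1, config.replicates + 1):
                rows.append({"sample": f"{strain}_pH{ph}_r{rep}", "strain": strain, "pH": ph, "replicate": rep})
    sheet = pd.DataFrame(rows).set_index("sample")
    meta = SampleMetadata(table=sheet)
    sample_ids = list(sheet.index)

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=config.n_genes)
    fc, drop = config.planted_log10_fc, config.gating_drop
    conditions = [(s, p) for s in config.strains for p in config.ph_levels]
    effect = {
        (arch, s, p): _condition_effect(arch, s, p, fc, drop)
        for arch in ARCHETYPES
        for (s, p) in conditions
    }

    true_conc = np.empty((config.n_genes, len(sample_ids)))
    for j, sample in enumerate(sample_ids):
        strain, ph = sheet.loc[sample, "strain"], int(sheet.loc[sample, "pH"])
        eff = np.array([effect[(a, strain, ph)] for a in labels])
        true_conc[:, j] = baseline + eff

    # Gene variances from a scaled inverse-chi-square prior.
    if config.s0_true2 > 0:
        sigma2 = config.d0_true * config.s0_true2 / rng.chisquare(config.d0_true, size=config.n_genes)
    else:
        sigma2 = np.zeros(config.n_genes)

    slope = rng.uniform(*config.slope_range, size=len(sample_ids))
    offset = rng.uniform(*config.offset_range, size=len(sample_ids))

    noise = rng.standard_normal((config.n_genes, len(sample_ids))) * np.sqrt(sigma2)[:, None]
    log_signal = config.signal_scale + true_conc * slope[None, :] + offset[None, :] + noise

    spike_conc = spikes.log10_concentration.to_numpy()
    spike_log_signal = config.signal_scale + spike_conc[:, None] * slope[None, :] + offset[None, :]

    all_ids = list(spikes.spike_ids) + gene_ids
    values = pd.DataFrame(
        np.power(10.0, np.vstack([spike_log_signal, log_signal])),
        index=pd.Index(all_ids, name="gene_id"),
        columns=sample_ids,
    )
    flags = pd.Series([True] * len(spikes) + [False] * config.n_genes, index=values.index)
    matrix = ExpressionMatrix(values=values, spike_flags=flags, scale="raw")

    cond_effect = pd.DataFrame(
        {condition_label(s, p): [effect[(a, s, p)] for a in labels] for (s, p) in conditions},
        index=gene_ids,
    )
    fc_cols = {}
    for name, (ca, cb) in DEFAULT_CONTRASTS.items():
        if ca in cond_effect.columns and cb in cond_effect.columns:
            fc_cols[name] = cond_effect[ca] - cond_effect[cb]
    truth = GroundTruth(
        archetype=archetype,
        true_log10_fc=pd.DataFrame(fc_cols),
        sample_slope=pd.Series(slope, index=sample_ids),
        sample_offset=pd.Series(offset, index=sample_ids),
        true_log_concentration=pd.DataFrame(true_conc, index=gene_ids, columns=sample_ids),
        gene_sigma2=pd.Series(sigma2, index=gene_ids),
        d0_true=config.d0_true,
        s0_true2=config.s0_true2,
    )
    return matrix, meta, spikes, truth


def noise_free(config: SyntheticConfig) -> SyntheticConfig:
    """Copy of a config with gene noise switched off."""
    return replace(config, s0_true2=0.0)


def undistorted(config: SyntheticConfig) -> SyntheticConfig:
    """Copy of a config with identity per-sample distortions."""
    return replace(config, slope_range=(1.0, 1.0), offset_range=(0.0, 0.0))


def generate_promoter_set(
    n: int,
    length: int = 1000,
    gc: float = 0.5,
    planted: Mapping[str, tuple[int, int]] | None = None,
    seed: int = 0,
    motif: str = "GCCARG",
    gene_ids: list[str] | None = None,
    members: Mapping[str, set[str]] | None = None,
) -> tuple[PromoterSet, dict[str, set[str]], pd.Series]:
    """Random promoters with optional planted motif instances.

    Background bases are i.i.d. with P(G) = P(C) = gc/2. ``planted`` maps a
    set label to ``(n_promoters, sites_per_promoter)``; planted instances of
    the (degenerate) motif are inserted at non-overlapping positions on a
    random strand, degenerate positions resolved uniformly at random.
    ``gene_ids`` names the promoters (default ``p00001``...); ``members``
    optionally pins a planted set to specific gene ids instead of a random
    draw (the per-promoter site count still comes from ``planted``).

    Returns the promoters, set-label -> member gene ids, and the per-gene
    planted site counts.
    """
    if not 0 < gc < 1:
        raise ValidationError("gc must be in (0, 1)")
    mlen = len(motif)
    if length < mlen:
        raise ValidationError("promoter length must be >= motif length")
    rng = np.random.default_rng(seed)
    planted = dict(planted or {})
    n_planted_total = sum(sz for sz, _ in planted.values())
    if n_planted_total > n:
        raise ValidationError("more promoters requested in planted sets than generated")

    bases = np.array(list("ACGT"))
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    if gene_ids is None:
        gene_ids = [f"p{i + 1:05d}" for i in range(n)]
    elif len(gene_ids) != n:
        raise ValidationError(f"gene_ids has {len(gene_ids)} entries for n={n}")
    seqs = rng.choice(bases, size=(n, length), p=probs)

    membership: dict[str, set[str]] = {}
    planted_counts = pd.Series(0, index=gene_ids, dtype=int)
    order = rng.permutation(n)
    pos = 0
    rc = {"A": "T", "C": "G", "G": "C", "T": "A"}
    for label, (size, sites) in planted.items():
        if members is not None and label in members:
            chosen = sorted(members[label])
            missing = set(chosen) - set(gene_ids)
            if missing:
                raise ValidationError(f"planted members absent from gene_ids: {sorted(missing)[:5]}")
        else:
            chosen = [gene_ids[k] for k in order[pos : pos + size]]
            pos += size
        membership[label] = set(chosen)
        max_slots = length // mlen
        if sites > max_slots:
            raise ValidationError(
                f"cannot place {sites} non-overlapping {mlen}-mers in {length} nt"
            )
        index_of = {g: i for i, g in enumerate(gene_ids)}
        for gene in chosen:
            gi = index_of[gene]
            # Non-overlapping placement: pick starts on a shuffled grid of
            # disjoint motif-length slots.
            slots = rng.permutation(max_slots)[:sites]
            for slot in slots:
                start = slot * mlen
                inst = "".join(
                    ch if len(expand_iupac(ch)) == 1 else rng.choice(sorted(expand_iupac(ch)))
                    for ch in motif
                )
                if rng.random() < 0.5:  # reverse strand
                    inst = "".join(rc[c] for c in reversed(inst))
                seqs[gi, start : start + mlen] = list(inst)
            planted_counts[gene] = sites
    promoters = PromoterSet(sequences={g: "".join(row) for g, row in zip(gene_ids, seqs)})
    return promoters, membership, planted_counts


def generate_kog_annotation(
    n_genes: int,
    classes: Mapping[str, float],
    target_set: set[str] | None = None,
    enrichment_factor: float = 1.0,
    enriched_class: str | None = None,
    seed: int = 0,
    gene_ids: list[str] | None = None,
) -> tuple[KogAnnotation, dict[str, float]]:
    """Sample a multi-label KOG annotation with one optionally enriched class.

    ``classes`` maps class label -> baseline membership probability. Genes in
    ``target_set`` get probability ``min(1, factor * p)`` for the enriched
    class (default: the first class listed). Returns the annotation and the
    per-class truth (the planted enrichment factor; 1.0 elsewhere).
    """
    if enrichment_factor <= 0:
        raise ValidationError("enrichment_factor must be > 0")
    rng = np.random.default_rng(seed)
    if gene_ids is None:
        gene_ids = [f"g{i + 1:05d}" for i in range(n_genes)]
    target_set = set(target_set or ())
    if enriched_class is None:
        enriched_class = next(iter(classes))
    if enriched_class not in classes:
        raise ValidationError(f"enriched class {enriched_class!r} not among classes")
    if enrichment_factor * classes[enriched_class] > 1.0:
        raise ValidationError(
            f"factor {enrichment_factor} incompatible with class prevalence "
            f"{classes[enriched_class]} (probability would exceed 1)"
        )
    annot: dict[str, frozenset[str]] = {}
    for gene in gene_ids:
        labels = set()
        for cls, p in classes.items():
            prob = p * enrichment_factor if (cls == enriched_class and gene in target_set) else p
            if rng.random() < prob:
                labels.add(cls)
        annot[gene] = frozenset(labels)
    truth = {cls: (enrichment_factor if cls == enriched_class else 1.0) for cls in classes}
    return KogAnnotation(classes=annot, vocabulary=frozenset(classes)), truth
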