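"""Degenerate-motif scanning and promoter density enrichment.

The consensus PacC binding site is 5'-GCCARG-3' (R = purine). Scanning is
overlap-tolerant (the motif self-overlaps at offset 5) and by default counts
both strands: a hit on the reverse strand appears in the given sequence as
the reverse complement pattern (CYTGGC). Density is sites per kb of scanned
promoter sequence; enrichment of a gene set is judged against same-size
random gene sets drawn from the promoter universe.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import IUPAC_CODES, PromoterSet, ValidationError

_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


def expand_iupac(code: str) -> frozenset[str]:
    """Concrete bases matched by one IUPAC code."""
    try:
        return IUPAC_CODES[code.upper()]
    except KeyError:
        raise ValidationError(f"invalid IUPAC code {code!r}") from None


def reverse_complement(pattern: str) -> str:
    try:
        return "".join(_COMPLEMENT[c] for c in reversed(pattern.upper()))
    except KeyError as exc:
        raise ValidationError(f"invalid IUPAC code in {pattern!r}: {exc}") from None


def _regex(pattern: str) -> re.Pattern:
    # Character classes list concrete bases only, so N in the *sequence*
    # never matches (an ambiguous observed base is not evidence of a site).
    parts = []
    for code in pattern.upper():
        bases = sorted(expand_iupac(code))
        parts.append(bases[0] if len(bases) == 1 else "[" + "".join(bases) + "]")
    # Lookahead makes counting overlap-tolerant.
    return re.compile("(?=" + "".join(parts) + ")")


@dataclass
class MotifSpec:
    """A degenerate motif and how to scan it."""

    pattern: str = "GCCARG"
    strands: str = "both"  # "forward" or "both"
    window: int = 1000     # nominal upstream window length, nt

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValidationError("empty motif pattern")
        for c in self.pattern.upper():
            expand_iupac(c)
        if self.strands not in ("forward", "both"):
            raise ValidationError("strands must be 'forward' or 'both'")


def scan_motif(sequence: str, spec: MotifSpec) -> list[tuple[int, str]]:
    """All (0-based position, strand) matches of the motif in ``sequence``.

    Reverse-strand hits are located by matching the reverse-complement
    pattern in the given sequence; the reported position is the start of the
    matched window on the given (coding) strand.
    """
    seq = sequence.upper()
    hits = [(m.start(), "+") for m in _regex(spec.pattern).finditer(seq)]
    if spec.strands == "both":
        rc = reverse_complement(spec.pattern)
        hits += [(m.start(), "-") for m in _regex(rc).finditer(seq)]
    return sorted(hits)


def count_motif(sequence: str, spec: MotifSpec) -> int:
    return len(scan_motif(sequence, spec))


def per_gene_counts(promoters: PromoterSet, spec: MotifSpec) -> pd.Series:
    """Motif count per promoter, over the whole promoter set."""
    return pd.Series(
        {g: count_motif(s, spec) for g, s in promoters.sequences.items()}, dtype=int
    ).rename("sites")


@dataclass
class MotifDensityResult:
    """Per-set motif density with its resampled background."""

    counts: pd.Series            # per-gene site counts in the query set
    total_sites: int
    total_kb: float
    density: float               # sites per kb
    background_densities: np.ndarray = field(default_factory=lambda: np.empty(0))
    background_mean: float = float("nan")
    background_sd: float = float("nan")
    pvalue: float = float("nan")
    seed: int | None = None
    missing_genes: list[str] = field(default_factory=list)


def upstream_density(
    promoters: PromoterSet,
    gene_set: set[str],
    spec: MotifSpec | None = None,
    counts: pd.Series | None = None,
) -> MotifDensityResult:
    """Site density (per kb) over a gene set's promoters.

    Promoters shorter than the nominal window contribute their actual length
    to the denominator. Genes without a promoter are recorded and skipped.
    ``counts`` may carry precomputed per-gene counts to avoid rescanning.
    """
    spec = spec or MotifSpec()
    present = [g for g in sorted(gene_set, key=str) if g in promoters]
    missing = [g for g in sorted(gene_set, key=str) if g not in promoters]
    if not present:
        raise ValidationError("no gene in the set has a promoter sequence")
    if counts is None:
        set_counts = pd.Series({g: count_motif(promoters.sequences[g], spec) for g in present}, dtype=int)
    else:
        set_counts = counts.loc[present].astype(int)
    total = int(set_counts.sum())
    kb = float(promoters.lengths.loc[present].sum()) / 1000.0
    return MotifDensityResult(
        counts=set_counts,
        total_sites=total,
        total_kb=kb,
        density=total / kb,
        missing_genes=missing,
    )


def background_density(
    promoters: PromoterSet,
    set_size: int,
    n_draws: int = 1000,
    seed: int = 0,
    exclude: set[str] | None = None,
    spec: MotifSpec | None = None,
    counts: pd.Series | None = None,
) -> np.ndarray:
    """Densities of ``n_draws`` random same-size gene sets from the universe.

    Sets are drawn without replacement from the promoter universe minus
    ``exclude`` (normally the query set). Returns the per-draw densities.
    """
    spec = spec or MotifSpec()
    pool = [g for g in promoters.gene_ids if not (exclude and g in exclude)]
    if len(pool) < set_size:
        raise ValidationError(
            f"promoter universe ({len(pool)} after exclusions) smaller than set size {set_size}"
        )
    if counts is None:
        counts = per_gene_counts(promoters, spec)
    cnt = counts.loc[pool].to_numpy(dtype=float)
    kb = promoters.lengths.loc[pool].to_numpy(dtype=float) / 1000.0
    rng = np.random.default_rng(seed)
    out = np.empty(n_draws)
    for i in range(n_draws):
        idx = rng.choice(len(pool), size=set_size, replace=False)
        out[i] = cnt[idx].sum() / kb[idx].sum()
    return out


def enrichment_pvalue(observed_density: float, background: np.ndarray) -> float:
    """One-sided permutation P with the add-one correction."""
    if background.size == 0:
        raise ValidationError("empty background distribution")
    return (1.0 + int(np.sum(background >= observed_density))) / (background.size + 1.0)


def motif_enrichment(
    promoters: PromoterSet,
    gene_set: set[str],
    spec: MotifSpec | None = None,
    n_draws: int = 1000,
    seed: int = 0,
) -> MotifDensityResult:
    """Density of a gene set plus resampled background and permutation P."""
    spec = spec or MotifSpec()
    counts = per_gene_counts(promoters, spec)
    result = upstream_density(promoters, gene_set, spec, counts=counts)
    bg = background_density(
        promoters, set_size=len(result.counts), n_draws=n_draws, seed=seed,
        exclude=gene_set, spec=spec, counts=counts,
    )
    result.background_densities = bg
    result.background_mean = float(bg.mean())
    result.background_sd = float(bg.std(ddof=1)) if bg.size > 1 else 0.0
    result.pvalue = enrichment_pvalue(result.density, bg)
    result.seed = seed
    return result


def expected_uniform_density(length: int = 1000, pattern: str = "GCCARG", strands: str = "both") -> float:
    """Closed-form expected density (per kb) on i.i.d. uniform sequence."""
    p = 1.0
    for code in pattern.upper():
        p *= len(expand_iupac(code)) / 4.0
    n_pos = length - len(pattern) + 1
    factor = 2.0 if strands == "both" else 1.0
    return factor * n_pos * p / (length / 1000.0)
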