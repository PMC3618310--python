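"""Expected-vs-observed KOG functional-class enrichment.

For a selected gene set S drawn from an annotated universe of N genes, a
class with K members is expected to contribute e = |S| * K / N genes to the
selection. The observed count o is compared with a two-sided hypergeometric
test (doubled smaller tail, capped at 1), so both enrichment (o > e) and
deficiency (o < e) are reported. Genes carrying several classes count once
per class; N counts genes, not annotations. Unannotated genes are excluded
from both the universe and the selection (and counted in the output).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .containers import KogAnnotation, ValidationError
from .de import adjust_bh


def expected_counts(
    annotation: KogAnnotation,
    selected: Iterable[str],
    universe: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Observed and expected per-class counts for a gene selection.

    Returns a DataFrame indexed by class with columns observed, expected,
    class_size; attrs record N (annotated universe), n_selected (annotated
    selection) and how many genes were dropped as unannotated.
    """
    selected = set(selected)
    universe_list = list(universe) if universe is not None else list(annotation.classes)
    not_in_universe = selected - set(universe_list)
    if not_in_universe:
        raise ValidationError(
            f"selected genes outside the universe: {sorted(not_in_universe)[:5]} ..."
            if len(not_in_universe) > 5
            else f"selected genes outside the universe: {sorted(not_in_universe)}"
        )
    annotated_universe = annotation.annotated_genes(universe_list)
    n_total = len(annotated_universe)
    sel_annotated = [g for g in annotated_universe if g in selected]
    if not sel_annotated or not n_total:
        raise ValidationError("empty annotated selection or universe")
    members = annotation.class_members(annotated_universe)
    rows = {}
    n_sel = len(sel_annotated)
    for cls in sorted(members):
        k = len(members[cls])
        o = len(members[cls] & selected)
        rows[cls] = {
            "observed": o,
            "expected": n_sel * k / n_total,
            "class_size": k,
        }
    out = pd.DataFrame(rows).T
    out.index.name = "kog_class"
    out["observed"] = out["observed"].astype(int)
    out["class_size"] = out["class_size"].astype(int)
    out.attrs["N"] = n_total
    out.attrs["n_selected"] = n_sel
    out.attrs["n_unannotated_selected"] = len(selected) - n_sel
    return out


def enrich_test(o: int, K: int, n_selected: int, N: int) -> tuple[float, str]:
    """Two-sided hypergeometric P and direction for one class.

    P = min(1, 2 * min(P[X <= o], P[X >= o])) with X ~ Hypergeom(N, K, |S|);
    direction is the sign of o - e ('ns' when o equals e exactly).
    """
    if not (0 <= o <= min(K, n_selected)) or K > N or n_selected > N:
        raise ValidationError(
            f"inconsistent counts: o={o}, K={K}, |S|={n_selected}, N={N}"
        )
    dist = hypergeom(N, K, n_selected)
    p_low = dist.cdf(o)
    p_high = dist.sf(o - 1)
    p = min(1.0, 2.0 * min(p_low, p_high))
    e = n_selected * K / N
    if o > e:
        direction = "enriched"
    elif o < e:
        direction = "deficient"
    else:
        direction = "ns"
    return float(p), direction


@dataclass
class EnrichmentResult:
    """Per-class enrichment table plus the counts it was computed from."""

    table: pd.DataFrame  # class x (observed, expected, class_size, ratio, pvalue, adj_pvalue, direction, significant)
    n_universe: int
    n_selected: int
    n_unannotated_selected: int


def kog_enrichment(
    annotation: KogAnnotation,
    selected: Iterable[str],
    universe: Iterable[str] | None = None,
    alpha: float = 0.05,
) -> EnrichmentResult:
    """Full expected-vs-observed analysis over every annotated class."""
    counts = expected_counts(annotation, selected, universe)
    n_total = counts.attrs["N"]
    n_sel = counts.attrs["n_selected"]
    pvals, directions = [], []
    for cls, row in counts.iterrows():
        p, d = enrich_test(int(row["observed"]), int(row["class_size"]), n_sel, n_total)
        pvals.append(p)
        directions.append(d)
    table = counts.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        table["ratio"] = table["observed"] / table["expected"]
    table["pvalue"] = pvals
    table["adj_pvalue"] = adjust_bh(np.asarray(pvals))
    table["direction"] = directions
    table["significant"] = table["adj_pvalue"] < alpha
    return EnrichmentResult(
        table=table,
        n_universe=n_total,
        n_selected=n_sel,
        n_unannotated_selected=counts.attrs["n_unannotated_selected"],
    )
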