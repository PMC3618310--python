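"""Regulon classes from contrast-call intersections, and profile clustering.

The biology: a zinc-finger transcription factor (PacC/Rim101) is activated
at alkaline ambient pH. Comparing wild type and the deletion mutant across a
pH-4 -> pH-8 step lets call vectors over four contrasts define named gene
sets:

* per-strain pH response and their Venn overlap (wt-only / shared /
  mutant-only, per direction);
* PacC-dependent sets: alkaline-induced in wt AND higher in wt than mutant
  at pH 8 (and the mirrored down class);
* acid-regulated sets: strain-differential at pH 4 only — unexpected because
  the factor is not proteolytically activated at acid pH;
* gating sets: pH-responsive in *both* strains with concordant direction,
  but expressed at a significantly lower level in the mutant — the factor
  gates amplitude rather than direction.

Averaged condition profiles are clustered agglomeratively with
Pearson-correlation distance (1 - r) and average linkage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .containers import ValidationError

logger = logging.getLogger(__name__)


def _check_universe(*calls: pd.Series) -> None:
    first = calls[0].index
    for c in calls[1:]:
        if not first.equals(c.index):
            raise ValidationError("call vectors are over different gene universes")


def _called(calls: pd.Series, direction: str) -> set[str]:
    return set(calls.index[calls == direction])


@dataclass
class RegulonClasses:
    """Named gene sets derived from the four contrasts."""

    sets: dict[str, set[str]]

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]

    def sizes(self) -> pd.Series:
        return pd.Series({k: len(v) for k, v in self.sets.items()}, dtype=int)


def build_venn_classes(calls_wt: pd.Series, calls_mut: pd.Series) -> dict[str, set[str]]:
    """Venn cells of the per-strain pH responses, per direction.

    ``calls_wt`` is the wt pH8-vs-pH4 call vector, ``calls_mut`` the mutant's.
    Returns wt_only / shared / mut_only sets for each direction plus the
    per-strain sets themselves.
    """
    _check_universe(calls_wt, calls_mut)
    out: dict[str, set[str]] = {}
    for direction in ("up", "down"):
        wt = _called(calls_wt, direction)
        mut = _called(calls_mut, direction)
        out[f"wt_{direction}"] = wt
        out[f"mut_{direction}"] = mut
        out[f"wt_only_{direction}"] = wt - mut
        out[f"shared_{direction}"] = wt & mut
        out[f"mut_only_{direction}"] = mut - wt
    return out


def classify_pacc_dependence(
    calls_wt_ph: pd.Series,
    calls_wt8_vs_mut8: pd.Series,
) -> tuple[set[str], set[str]]:
    """PacC-dependent up/down sets.

    pacc_up: up in wt pH8 vs pH4 AND up in wt vs mutant at pH 8 (the
    alkaline induction requires the factor). pacc_down mirrors with down
    calls in both contrasts.
    """
    _check_universe(calls_wt_ph, calls_wt8_vs_mut8)
    pacc_up = _called(calls_wt_ph, "up") & _called(calls_wt8_vs_mut8, "up")
    pacc_down = _called(calls_wt_ph, "down") & _called(calls_wt8_vs_mut8, "down")
    return pacc_up, pacc_down


def classify_acid_and_gating(
    calls: Mapping[str, pd.Series],
    means: pd.DataFrame | None = None,
) -> dict[str, set[str]]:
    """Acid-regulated and gating sets from the four contrasts.

    ``calls`` must contain 'wt8_vs_wt4', 'mut8_vs_mut4', 'wt8_vs_mut8' and
    'wt4_vs_mut4' call vectors (fold change oriented first-vs-second).

    * acid_up — higher in the mutant at pH 4 (call 'down' in wt4_vs_mut4);
      acid_down — lower in the mutant at pH 4.
    * gating_up — pH-up call in both strains AND wt significantly above the
      mutant at pH 8 (the pH of elevated expression); gating_down — pH-down
      in both strains AND wt above the mutant at pH 4.
    """
    needed = ("wt8_vs_wt4", "mut8_vs_mut4", "wt8_vs_mut8", "wt4_vs_mut4")
    missing = [n for n in needed if n not in calls]
    if missing:
        raise ValidationError(f"missing contrasts: {missing}")
    _check_universe(*[calls[n] for n in needed])
    acid_up = _called(calls["wt4_vs_mut4"], "down")    # mutant pH4 > wt pH4
    acid_down = _called(calls["wt4_vs_mut4"], "up")    # mutant pH4 < wt pH4
    gating_up = (
        _called(calls["wt8_vs_wt4"], "up")
        & _called(calls["mut8_vs_mut4"], "up")
        & _called(calls["wt8_vs_mut8"], "up")
    )
    gating_down = (
        _called(calls["wt8_vs_wt4"], "down")
        & _called(calls["mut8_vs_mut4"], "down")
        & _called(calls["wt4_vs_mut4"], "up")
    )
    return {
        "acid_up": acid_up,
        "acid_down": acid_down,
        "gating_up": gating_up,
        "gating_down": gating_down,
    }


def classify_all(
    calls: Mapping[str, pd.Series],
    means: pd.DataFrame | None = None,
) -> RegulonClasses:
    """All named classes from the four contrast call vectors.

    Genes with a missing call in any contrast are excluded and logged.
    """
    needed = ("wt8_vs_wt4", "mut8_vs_mut4", "wt8_vs_mut8", "wt4_vs_mut4")
    missing = [n for n in needed if n not in calls]
    if missing:
        raise ValidationError(f"missing contrasts: {missing}")
    common = calls[needed[0]].index
    for n in needed[1:]:
        common = common.intersection(calls[n].index)
    dropped = set().union(*(set(calls[n].index) for n in needed)) - set(common)
    if dropped:
        logger.warning("%d gene(s) excluded from classification (missing calls)", len(dropped))
    trimmed = {n: calls[n].loc[common] for n in needed}
    sets = build_venn_classes(trimmed["wt8_vs_wt4"], trimmed["mut8_vs_mut4"])
    pacc_up, pacc_down = classify_pacc_dependence(trimmed["wt8_vs_wt4"], trimmed["wt8_vs_mut8"])
    sets["pacc_up"], sets["pacc_down"] = pacc_up, pacc_down
    sets.update(classify_acid_and_gating(trimmed, means))
    return RegulonClasses(sets=sets)


@dataclass
class ProfileClusters:
    """Z-scored condition profiles with cluster labels and centroids."""

    profiles: pd.DataFrame       # genes x conditions, standardized
    labels: pd.Series            # gene -> cluster id (1..k)
    centroids: pd.DataFrame      # cluster x conditions, standardized
    excluded: list[str]          # constant-profile genes left unclustered


def cluster_average_profiles(
    means: pd.DataFrame,
    k: int = 6,
    standardize: bool = True,
) -> ProfileClusters:
    """Agglomerative clustering of averaged condition profiles.

    Profiles are row z-scored (so clustering sees shape, not level),
    distance is 1 - Pearson r, linkage is average, and the tree is cut to
    ``k`` clusters. Constant profiles have undefined correlation and are
    excluded with a warning.
    """
    sd = means.std(axis=1, ddof=0)
    constant = sd <= 0
    excluded = list(means.index[constant])
    if excluded:
        logger.warning("%d constant profile(s) excluded from clustering", len(excluded))
    data = means.loc[~constant]
    if len(data) < k:
        raise ValidationError(f"need >= k={k} non-constant profiles, got {len(data)}")
    if standardize:
        z = data.sub(data.mean(axis=1), axis=0).div(data.std(axis=1, ddof=0), axis=0)
    else:
        z = data
    link = linkage(z.to_numpy(), method="average", metric="correlation")
    labels = pd.Series(fcluster(link, t=k, criterion="maxclust"), index=z.index, name="cluster")
    centroids = {}
    for c in sorted(labels.unique()):
        centroid = z.loc[labels == c].mean(axis=0)
        if standardize:
            s = centroid.std(ddof=0)
            centroid = (centroid - centroid.mean()) / (s if s > 0 else 1.0)
        centroids[c] = centroid
    return ProfileClusters(
        profiles=z,
        labels=labels,
        centroids=pd.DataFrame(centroids).T,
        excluded=excluded,
    )


def correlation_distance(a: np.ndarray, b: np.ndarray) -> float:
    """1 - Pearson r between two profiles (0 identical, 2 anti-correlated)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.std() == 0 or b.std() == 0:
        raise ValidationError("correlation distance undefined for constant profiles")
    return float(1.0 - np.corrcoef(a, b)[0, 1])
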