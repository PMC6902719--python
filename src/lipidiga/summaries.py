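"""Derived study summaries: RBC fatty acids, precursor totals, correlations.

These are the headline quantities of a supplementation study: the n-3
index (erythrocyte EPA% + DHA%, a compliance/bioavailability biomarker),
per-fatty-acid paired tests, per-subject precursor-metabolite totals with
percent change, and a Spearman screen of skin-plasma concordance used to
judge whether plasma mediator levels can proxy for cutaneous ones.
"""

from __future__ import annotations

import logging
from itertools import permutations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .difftest import paired_t_test
from .panel import MediatorPanel
from .preprocess import ConcentrationMatrix

logger = logging.getLogger(__name__)

EPA_FA = "20:5n-3"
DHA_FA = "22:6n-3"


def n3_index(profile: Mapping[str, float] | pd.Series) -> float:
    """n-3 index: EPA (20:5n-3) weight-% plus DHA (22:6n-3) weight-%."""
    try:
        return float(profile[EPA_FA]) + float(profile[DHA_FA])
    except KeyError as exc:
        raise ValueError(f"profile lacks fatty acid {exc.args[0]!r}") from exc


def fatty_acid_paired_tests(profiles: pd.DataFrame) -> pd.DataFrame:
    """Paired pre/post t test per fatty acid, uncorrected.

    ``profiles`` has columns ``subject``, ``phase`` plus one column per
    fatty acid.  Subjects lacking either phase are excluded with a
    warning.  Returns one row per fatty acid: mean_pre, mean_post, t, p.
    """
    fa_cols = [c for c in profiles.columns if c not in ("subject", "phase", "arm")]
    wide = {
        phase: profiles[profiles["phase"] == phase].set_index("subject")[fa_cols]
        for phase in ("pre", "post")
    }
    common = wide["pre"].index.intersection(wide["post"].index)
    unpaired = wide["pre"].index.symmetric_difference(wide["post"].index)
    if len(unpaired):
        logger.warning("excluding unpaired subjects: %s", list(unpaired))
    pre, post = wide["pre"].loc[common], wide["post"].loc[common]
    rows = []
    for fa in fa_cols:
        t, p = paired_t_test((post[fa] - pre[fa]).to_numpy())
        rows.append(
            {
                "fatty_acid": fa,
                "n": len(common),
                "mean_pre": float(pre[fa].mean()),
                "mean_post": float(post[fa].mean()),
                "t": t,
                "p": p,
            }
        )
    return pd.DataFrame(rows)


def precursor_totals(
    matrix: ConcentrationMatrix,
    panel: MediatorPanel,
    precursor: str,
    condition: Mapping[str, str] | None = None,
) -> pd.Series:
    """Per-subject sum of raw concentrations of one precursor's metabolites.

    ``condition`` filters design rows (e.g. ``{"phase": "pre",
    "uvr_time": "unirradiated"}``).  Run after LOD substitution so missing
    cells contribute the LOD; raw units are kept (pg/mg protein or pg/ml).
    """
    species = [n for n in matrix.species if n in panel and panel[n].precursor == precursor]
    if not species:
        raise ValueError(f"no species with precursor {precursor!r} in matrix")
    design = matrix.design
    mask = pd.Series(True, index=design.index)
    for col, val in (condition or {}).items():
        mask &= design[col] == val
    sub = matrix.values.loc[mask.to_numpy(), species]
    totals = sub.sum(axis=1, skipna=True)
    totals.index = design.loc[mask.to_numpy(), "subject"]
    return totals.rename(f"{precursor}_total")


def percent_change(pre_totals: Sequence[float], post_totals: Sequence[float]) -> float:
    """100 * (mean post - mean pre) / mean pre, on the raw scale."""
    pre = float(np.mean(np.asarray(pre_totals, dtype=float)))
    post = float(np.mean(np.asarray(post_totals, dtype=float)))
    if pre <= 0:
        raise ValueError("mean pre-total must be positive")
    return 100.0 * (post - pre) / pre


# ---------------------------------------------------------------------------
# Skin-plasma correlation screen
# ---------------------------------------------------------------------------


def _spearman_exact_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided exact permutation p for Spearman rho (enumerates all n!)."""
    ra = stats.rankdata(a)
    rb = stats.rankdata(b)
    obs = abs(_rank_corr(ra, rb))
    count = 0
    total = 0
    for perm in permutations(rb):
        total += 1
        if abs(_rank_corr(ra, np.asarray(perm))) >= obs - 1e-12:
            count += 1
    return count / total


def _rank_corr(ra: np.ndarray, rb: np.ndarray) -> float:
    ra = ra - ra.mean()
    rb = rb - rb.mean()
    denom = np.sqrt((ra**2).sum() * (rb**2).sum())
    if denom == 0:
        return np.nan
    return float((ra * rb).sum() / denom)


def spearman_cross_compartment(
    skin: ConcentrationMatrix,
    plasma: ConcentrationMatrix,
    pairing: Sequence[str] = ("subject", "phase"),
    exact_max_n: int = 9,
) -> pd.DataFrame:
    """Spearman correlation per species between skin and plasma levels.

    Samples are paired on ``pairing`` keys (subject and phase by default);
    skin UVR-challenged samples are excluded so both compartments reflect
    the same unchallenged state.  Exact permutation p values are used for
    n <= ``exact_max_n``, the large-sample t approximation otherwise.
    Species constant in either compartment get rho = NaN with a note.
    """
    pairing = list(pairing)

    def keyed(matrix: ConcentrationMatrix) -> pd.DataFrame:
        design = matrix.design
        mask = (design["uvr_time"] == "unirradiated").to_numpy()
        vals = matrix.values.loc[mask]
        keys = design.loc[mask, pairing]
        vals = vals.set_axis(pd.MultiIndex.from_frame(keys), axis=0)
        return vals[~vals.index.duplicated()]

    skin_v, plasma_v = keyed(skin), keyed(plasma)
    common_samples = skin_v.index.intersection(plasma_v.index)
    common_species = [s for s in skin_v.columns if s in set(plasma_v.columns)]
    rows = []
    for sp in common_species:
        paired = pd.concat(
            [skin_v.loc[common_samples, sp], plasma_v.loc[common_samples, sp]],
            axis=1,
            keys=["skin", "plasma"],
        ).dropna()
        n = len(paired)
        if n < 3:
            rows.append({"species": sp, "rho": np.nan, "p": np.nan, "n": n, "note": "n<3"})
            continue
        a = paired["skin"].to_numpy()
        b = paired["plasma"].to_numpy()
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            rows.append(
                {"species": sp, "rho": np.nan, "p": np.nan, "n": n, "note": "constant"}
            )
            continue
        rho = _rank_corr(stats.rankdata(a), stats.rankdata(b))
        if n <= exact_max_n:
            p = _spearman_exact_p(a, b)
        else:
            p = float(stats.spearmanr(a, b).pvalue)
        rows.append({"species": sp, "rho": rho, "p": p, "n": n, "note": ""})
    return pd.DataFrame(rows, columns=["species", "rho", "p", "n", "note"])
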