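"""Paired univariate testing with Benjamini-Hochberg FDR control.

Each pairwise comparison is a within-subject contrast (e.g. pre- vs
post-supplementation, or unirradiated vs 24 h post-UVR) inside one arm and
tissue.  Species are tested with a two-tailed paired Student's t test on
glog2-transformed data; the mean paired difference on that scale is
reported as the log2 fold change (exact in the high-intensity limit).
P values are corrected with the Benjamini-Hochberg step-up procedure
within the comparison's species set, controlling FDR at 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

ALPHA = 0.05


@dataclass(frozen=True)
class PairwiseComparison:
    """A paired contrast: condition B vs condition A within arm x tissue.

    ``condition_a``/``condition_b`` map design columns (``phase``,
    ``uvr_time``) to required values; subjects pair the two sides.
    """

    arm: str
    tissue: str
    condition_a: Mapping[str, str]
    condition_b: Mapping[str, str]
    label: str = ""

    def __post_init__(self) -> None:
        if dict(self.condition_a) == dict(self.condition_b):
            raise ValueError("condition A and condition B must differ")
        if not self.label:
            object.__setattr__(self, "label", self._default_label())

    def _default_label(self) -> str:
        fmt = lambda c: "+".join(f"{v}" for v in c.values())
        return f"{self.arm}/{self.tissue}: {fmt(self.condition_b)} vs {fmt(self.condition_a)}"

    def _side_mask(self, design: pd.DataFrame, condition: Mapping[str, str]) -> pd.Series:
        mask = (design["arm"] == self.arm) & (design["tissue"] == self.tissue)
        for col, val in condition.items():
            mask &= design[col] == val
        return mask

    def mask_a(self, design: pd.DataFrame) -> pd.Series:
        return self._side_mask(design, self.condition_a)

    def mask_b(self, design: pd.DataFrame) -> pd.Series:
        return self._side_mask(design, self.condition_b)

    def select(self, design: pd.DataFrame) -> pd.Series:
        """Boolean mask of all samples on either side of the contrast."""
        return self.mask_a(design) | self.mask_b(design)


def paired_differences(
    transformed: pd.DataFrame,
    design: pd.DataFrame,
    comparison: PairwiseComparison,
) -> pd.DataFrame:
    """Per-subject differences d = B - A on the transformed scale.

    Returns a subjects x species table.  Subjects present on only one side
    are excluded with a warning; a subject contributing more than one
    sample to a side violates the paired design and raises.
    """
    design = design.loc[transformed.index]
    out = {}
    for side, mask in (("A", comparison.mask_a(design)), ("B", comparison.mask_b(design))):
        sub = transformed.loc[mask.to_numpy()]
        subjects = design.loc[mask.to_numpy(), "subject"]
        if subjects.duplicated().any():
            dups = subjects[subjects.duplicated()].unique().tolist()
            raise ValueError(
                f"subjects {dups} contribute multiple samples to side {side} "
                f"of {comparison.label!r}"
            )
        sub = sub.set_axis(subjects.to_numpy(), axis=0)
        out[side] = sub
    common = out["A"].index.intersection(out["B"].index)
    unpaired = out["A"].index.symmetric_difference(out["B"].index)
    if len(unpaired):
        logger.warning(
            "excluding unpaired subjects from %r: %s",
            comparison.label,
            list(unpaired),
        )
    if len(common) == 0:
        raise ValueError(f"no paired subjects for comparison {comparison.label!r}")
    return out["B"].loc[common] - out["A"].loc[common]


def paired_t_test(differences: np.ndarray | Sequence[float]) -> tuple[float, float]:
    """Two-tailed one-sample t test on paired differences.

    t = mean(d) / (sd(d)/sqrt(n)), df = n - 1.  Degenerate zero-variance
    vectors follow the no-signal convention: p = 1 when the mean is also
    zero, p = 0 (with a warning) when it is not.
    """
    d = np.asarray(differences, dtype=float)
    n = d.size
    if n < 2:
        raise ValueError("need at least 2 paired differences")
    mean = d.mean()
    sd = d.std(ddof=1)
    if sd == 0.0:
        if mean == 0.0:
            return 0.0, 1.0
        logger.warning("zero-variance differences with nonzero mean; p set to 0")
        return float(np.sign(mean) * np.inf), 0.0
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return float(t), float(min(p, 1.0))


def bh_adjust(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (q values), capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class SpeciesTestTable:
    """Per-species paired test results for one comparison."""

    comparison: PairwiseComparison
    table: pd.DataFrame
    removed: list[str] = field(default_factory=list)
    skipped: list[str] = field(default_factory=list)


def compile_results(
    comparison: PairwiseComparison,
    differences: pd.DataFrame,
    species_order: Sequence[str] | None = None,
    removed: Sequence[str] = (),
) -> SpeciesTestTable:
    """Run the paired t test per species, BH-adjust, and tabulate.

    One row per tested species with columns (species, n, log2fc, t, p, q,
    significant); rows follow ``species_order`` (panel order) when given.
    Species with fewer than 2 complete pairs are skipped and logged.
    """
    cols = list(differences.columns)
    if species_order is not None:
        order = [s for s in species_order if s in set(cols)]
        order += [s for s in cols if s not in set(order)]
        cols = order
    rows = []
    skipped: list[str] = []
    for sp in cols:
        d = differences[sp].dropna().to_numpy()
        if d.size < 2:
            skipped.append(sp)
            continue
        t, p = paired_t_test(d)
        rows.append({"species": sp, "n": int(d.size), "log2fc": float(d.mean()), "t": t, "p": p})
    if skipped:
        logger.warning("species skipped (<2 complete pairs): %s", skipped)
    table = pd.DataFrame(rows, columns=["species", "n", "log2fc", "t", "p"])
    if len(table):
        table["q"] = bh_adjust(table["p"].to_numpy())
        table["significant"] = table["q"] < ALPHA
    else:
        table["q"] = pd.Series(dtype=float)
        table["significant"] = pd.Series(dtype=bool)
    return SpeciesTestTable(
        comparison=comparison,
        table=table.reset_index(drop=True),
        removed=list(removed),
        skipped=skipped,
    )
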