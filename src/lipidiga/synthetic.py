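"""Synthetic paired-study generator for lipid-mediator panels.

Emulates a two-arm oral supplementation study (EPA n=12, DHA n=9) with
fully paired pre/post sampling of epidermis, dermis and plasma, and UVR
challenge timepoints (unirradiated, 24 h, 72 h) in skin.  Concentrations
follow an additive-plus-multiplicative error model around per-species,
per-tissue baseline medians:

    c = median * exp(u_subject) * effect * exp(eta) + eps,   truncated at 0,

with u_subject a log-scale between-subject effect shared across phases and
timepoints (so paired contrasts cancel it), eta log-scale measurement
noise, and eps additive noise in concentration units.  Values below the
species' limit of detection — set at a configurable quantile of the
baseline distribution — are recorded as missing, reproducing the
left-censoring real panels show.  Supplementation effects are injected as
multiplicative fold changes on named species or groups, forming the ground
truth for recovery tests.

Default baseline medians are anchored to the magnitudes targeted panels
report for human skin: epidermal EPA-derived mediators sum to ~319 and
DHA-derived mediators to ~3136 pg/mg protein, dermis runs ~3.3x lower,
and in plasma CYP450 epoxides/diols dominate while 2-AG is minor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .panel import GroupScheme, MediatorPanel
from .preprocess import ConcentrationMatrix

TISSUES = ("epidermis", "dermis", "plasma")
UVR_TIMEPOINTS = ("unirradiated", "24h", "72h")

# Epidermal anchors (pg/mg protein): EPA- and DHA-derived totals.
_EPA_TOTAL_EPIDERMIS = 319.0
_DHA_TOTAL_EPIDERMIS = 3136.0

_SKIN_PATHWAY_MEDIANS = {
    "COX": 400.0,
    "LOX": 800.0,
    "hybrid-monohydroxy": 800.0,
    "nonenzymatic": 300.0,
    "CYP450-epoxide": 300.0,
    "CYP450-diol": 100.0,
    "eCB": 150.0,
    "NAE": 500.0,
}
_SKIN_SPECIES_MEDIANS = {"2-AG": 3000.0, "AEA": 30.0}
_DERMIS_FACTOR = 0.3

_PLASMA_PATHWAY_MEDIANS = {
    "COX": 20.0,
    "LOX": 100.0,
    "hybrid-monohydroxy": 100.0,
    "nonenzymatic": 50.0,
    "CYP450-epoxide": 400.0,
    "CYP450-diol": 600.0,
    "eCB": 40.0,
    "NAE": 300.0,
}
_PLASMA_PRECURSOR_MONOHYDROXY = {"EPA": 30.0, "DHA": 120.0}
_PLASMA_SPECIES_MEDIANS = {"2-AG": 30.0, "AEA": 80.0, "PEA": 600.0, "OEA": 200.0}


def default_baseline_medians(panel: MediatorPanel) -> pd.DataFrame:
    """Species x tissue baseline medians (pg/mg protein skin, pg/ml plasma)."""
    skin_names = panel.species_in("skin")
    n_epa = sum(1 for n in skin_names if panel[n].precursor == "EPA")
    n_dha = sum(1 for n in skin_names if panel[n].precursor == "DHA")
    med = pd.DataFrame(np.nan, index=panel.names, columns=list(TISSUES))
    for sp in panel:
        if "skin" in sp.compartments:
            if sp.precursor == "EPA":
                epi = _EPA_TOTAL_EPIDERMIS / max(n_epa, 1)
            elif sp.precursor == "DHA":
                epi = _DHA_TOTAL_EPIDERMIS / max(n_dha, 1)
            else:
                epi = _SKIN_SPECIES_MEDIANS.get(sp.name, _SKIN_PATHWAY_MEDIANS[sp.pathway])
            med.loc[sp.name, "epidermis"] = epi
            med.loc[sp.name, "dermis"] = epi * _DERMIS_FACTOR
        if "plasma" in sp.compartments:
            if sp.name in _PLASMA_SPECIES_MEDIANS:
                pl = _PLASMA_SPECIES_MEDIANS[sp.name]
            elif sp.pathway in ("LOX", "hybrid-monohydroxy") and sp.precursor in _PLASMA_PRECURSOR_MONOHYDROXY:
                pl = _PLASMA_PRECURSOR_MONOHYDROXY[sp.precursor]
            else:
                pl = _PLASMA_PATHWAY_MEDIANS[sp.pathway]
            med.loc[sp.name, "plasma"] = pl
    return med


@dataclass(frozen=True)
class StudyConfig:
    """Design and noise parameters of a simulated supplementation study."""

    n_subjects_per_arm: Mapping[str, int] = field(
        default_factory=lambda: {"EPA": 12, "DHA": 9}
    )
    tissues: tuple[str, ...] = TISSUES
    uvr_timepoints: tuple[str, ...] = UVR_TIMEPOINTS
    baseline_medians: pd.DataFrame | None = None  # species x tissue; default panel-derived
    subject_sd: float = 0.4
    mult_noise_sd: float = 0.25
    add_noise_sd: float = 2.0
    lod_quantile: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("subject_sd", "mult_noise_sd", "add_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.lod_quantile < 1:
            raise ValueError("lod_quantile must be in [0, 1)")
        if any(n <= 0 for n in self.n_subjects_per_arm.values()):
            raise ValueError("subject counts must be positive")
        bad = set(self.tissues) - set(TISSUES)
        if bad or not self.tissues:
            raise ValueError(f"unknown tissues {bad}")
        bad = set(self.uvr_timepoints) - set(UVR_TIMEPOINTS)
        if bad or not self.uvr_timepoints:
            raise ValueError(f"unknown UVR timepoints {bad}")


@dataclass(frozen=True)
class EffectSpec:
    """A multiplicative ground-truth effect on a species or group.

    Applied to samples matching ``phase`` (and ``uvr_time`` / ``tissue``
    when given, any otherwise).  ``multiplier`` > 1 raises the targeted
    concentrations post-supplementation, < 1 lowers them.
    """

    target: str
    multiplier: float
    arm: str | None = None
    tissue: str | None = None
    phase: str = "post"
    uvr_time: str | None = None

    def __post_init__(self) -> None:
        if not self.multiplier > 0:
            raise ValueError("multiplier must be positive")

    def resolve(self, panel: MediatorPanel, scheme: GroupScheme | None) -> list[str]:
        if scheme is not None and self.target in scheme.groups:
            return list(scheme.groups[self.target])
        if self.target in panel:
            return [self.target]
        raise ValueError(f"effect target {self.target!r} matches no group or species")

    def applies(self, arm: str, tissue: str, phase: str, uvr_time: str) -> bool:
        return (
            (self.arm is None or self.arm == arm)
            and (self.tissue is None or self.tissue == tissue)
            and self.phase == phase
            and (self.uvr_time is None or self.uvr_time == uvr_time)
        )


@dataclass
class StudyDataset:
    """A generated study: design, per-tissue matrices, and the truth used."""

    design: pd.DataFrame
    matrices: dict[str, ConcentrationMatrix]
    truth: list[EffectSpec]
    config: StudyConfig

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.design.to_csv(outdir / "design.csv")
        for tissue, matrix in self.matrices.items():
            matrix.values.to_csv(outdir / f"{tissue}.csv")
            matrix.lod.rename("lod").to_csv(outdir / f"{tissue}_lod.csv")
        truth = [
            {k: v for k, v in vars(e).items() if v is not None} for e in self.truth
        ]
        (outdir / "truth.yaml").write_text(yaml.safe_dump(truth, sort_keys=False))


def _build_design(config: StudyConfig) -> pd.DataFrame:
    rows = []
    for arm, n in config.n_subjects_per_arm.items():
        for i in range(1, n + 1):
            subject = f"{arm}{i:02d}"
            for tissue in config.tissues:
                # plasma is sampled pre/post only, without UVR challenge
                timepoints = ("unirradiated",) if tissue == "plasma" else config.uvr_timepoints
                for uvr in timepoints:
                    for phase in ("pre", "post"):
                        rows.append(
                            {
                                "sample": f"{subject}-{tissue}-{phase}-{uvr}",
                                "subject": subject,
                                "arm": arm,
                                "phase": phase,
                                "tissue": tissue,
                                "uvr_time": uvr,
                            }
                        )
    return pd.DataFrame(rows).set_index("sample")


def generate_study(
    config: StudyConfig,
    effects: Sequence[EffectSpec] = (),
    panel: MediatorPanel | None = None,
    scheme: GroupScheme | None = None,
) -> StudyDataset:
    """Simulate a fully paired supplementation study.

    Every subject has both pre and post samples for every tissue x
    timepoint.  The same seed and config yield a bit-identical dataset.
    """
    if panel is None:
        from .panel import load_default_panel

        panel = load_default_panel()
    medians = (
        config.baseline_medians
        if config.baseline_medians is not None
        else default_baseline_medians(panel)
    )
    targets = {e: e.resolve(panel, scheme) for e in effects}
    design = _build_design(config)
    rng = np.random.default_rng(config.seed)
    sigma_base = float(np.hypot(config.subject_sd, config.mult_noise_sd))

    matrices: dict[str, ConcentrationMatrix] = {}
    for tissue in config.tissues:
        comp = "plasma" if tissue == "plasma" else "skin"
        species = [n for n in panel.species_in(comp) if pd.notna(medians.loc[n, tissue])]
        med = medians.loc[species, tissue].to_numpy(dtype=float)
        tdesign = design[design["tissue"] == tissue]
        subjects = tdesign["subject"].unique()
        # between-subject log-scale effects, shared across phase/timepoint
        u = {
            s: rng.normal(0.0, config.subject_sd, size=len(species)) for s in subjects
        }
        values = np.empty((len(tdesign), len(species)))
        for i, row in enumerate(tdesign.itertuples()):
            mult = np.ones(len(species))
            for eff, names in targets.items():
                if eff.applies(row.arm, tissue, row.phase, row.uvr_time):
                    idx = [j for j, n in enumerate(species) if n in set(names)]
                    mult[idx] *= eff.multiplier
            eta = rng.normal(0.0, config.mult_noise_sd, size=len(species))
            eps = rng.normal(0.0, config.add_noise_sd, size=len(species))
            values[i] = np.maximum(med * np.exp(u[row.subject]) * mult * np.exp(eta) + eps, 0.0)
        # LOD at the configured quantile of each species' baseline distribution
        if config.lod_quantile > 0:
            lod = med * np.exp(sigma_base * stats.norm.ppf(config.lod_quantile))
        else:
            lod = np.zeros(len(species))
        frame = pd.DataFrame(values, index=tdesign.index, columns=species)
        frame = frame.where(frame.to_numpy() > lod[None, :])
        matrices[tissue] = ConcentrationMatrix(
            design=tdesign,
            values=frame,
            lod=pd.Series(lod, index=species),
            unit="pg/ml" if tissue == "plasma" else "pg/mg-protein",
        )
    return StudyDataset(design=design, matrices=matrices, truth=list(effects), config=config)


# ---------------------------------------------------------------------------
# RBC fatty-acid profiles
# ---------------------------------------------------------------------------

#: Template pre-supplementation RBC composition (weight % of total FAs) for
#: an EPA arm whose n-3 index (EPA% + DHA%) averages 4.86.
DEFAULT_RBC_PRE_MEANS = {
    "16:0": 21.0,
    "18:0": 16.0,
    "18:1n-9": 14.0,
    "18:2n-6": 11.0,
    "20:4n-6": 13.0,
    "22:5n-3": 2.5,
    "20:5n-3": 1.0,
    "22:6n-3": 3.86,
}

#: Template post-pre shifts for the EPA arm: index rises 4.86 -> 7.67.
DEFAULT_RBC_EPA_SHIFT = {
    "20:5n-3": 2.51,
    "22:6n-3": 0.30,
    "22:5n-3": 0.80,
    "20:4n-6": -1.50,
}


def generate_rbc_profiles(
    n_subjects: int,
    pre_means: Mapping[str, float] = DEFAULT_RBC_PRE_MEANS,
    post_shift: Mapping[str, float] = DEFAULT_RBC_EPA_SHIFT,
    noise_sd: float = 0.3,
    seed: int = 0,
    arm: str = "EPA",
) -> pd.DataFrame:
    """Paired pre/post RBC fatty-acid weight-% profiles.

    Gaussian within-subject noise (sd ``noise_sd`` percentage points,
    clipped at 0) perturbs each fatty acid independently.  Raises if the
    template means are invalid (negative, sum > 100, or a shift driving a
    post mean negative).
    """
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    pre = pd.Series(pre_means, dtype=float)
    if (pre < 0).any() or pre.sum() > 100:
        raise ValueError("pre means must be nonnegative with total <= 100")
    unknown = set(post_shift) - set(pre.index)
    if unknown:
        raise ValueError(f"post_shift names absent from pre_means: {sorted(unknown)}")
    post = pre.add(pd.Series(post_shift, dtype=float), fill_value=0.0).loc[pre.index]
    if (post < 0).any():
        bad = post[post < 0].index.tolist()
        raise ValueError(f"shift drives fatty acids negative: {bad}")
    if post.sum() > 100:
        raise ValueError("post means must total <= 100")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(1, n_subjects + 1):
        subject = f"{arm}{i:02d}"
        for phase, means in (("pre", pre), ("post", post)):
            noise = rng.normal(0.0, noise_sd, size=len(means))
            vals = np.clip(means.to_numpy() + noise, 0.0, None)
            rows.append({"subject": subject, "phase": phase, **dict(zip(means.index, vals))})
    return pd.DataFrame(rows)
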