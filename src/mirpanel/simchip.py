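"""Synthetic serum-miRNA microarray chips and case/control cohorts.

Generates cohorts with the statistical structure the downstream pipeline
assumes: 2588-probe-style chips carrying target, negative-control and
internal-control spots; log2-normal signal noise on top of a per-sample
technical scale factor; planted case/control effect miRNAs; chips engineered
to fail quality control; clinical covariates (age, sex, smoking) linked to
case status through a logistic model so that propensity matching has real
work to do; and paired pre-/post-resection samples in which planted-marker
signals decay toward the non-cancer baseline after surgery.

Every draw comes from a single :class:`numpy.random.Generator` seeded from
``SimConfig.seed``, so a fixed configuration reproduces byte-identical
cohorts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "PlantedMarker",
    "CovariateModel",
    "SimConfig",
    "ChipProfile",
    "SampleMeta",
    "SimConfigError",
    "generate_cohort",
    "generate_prepost",
    "write_fixtures",
    "metas_to_frame",
    "frame_to_metas",
]

logger = logging.getLogger(__name__)

#: probe_type values used in chip tables
TARGET = "target"
NEGATIVE_CONTROL = "negative_control"
INTERNAL_CONTROL = "internal_control"

#: default internal-control miRNAs (endogenously stable normalizers)
DEFAULT_CONTROLS = ("miR-4463", "miR-2861", "miR-149-3p")

# Clinical category frequencies used when drawing cancer metadata.  Stage and
# histology marginals follow a large resectable-lung-cancer case series
# (adenocarcinoma-dominant, ~70% stage I).
_HISTOLOGY = ("adenocarcinoma", "squamous", "adenosquamous", "small_cell", "other")
_HISTOLOGY_P = (0.764, 0.152, 0.013, 0.016, 0.055)
_PSTAGE = ("IA", "IB", "IIA", "IIB", "IIIA", "IIIB", "IV", "0")
_PSTAGE_P = (0.55, 0.165, 0.075, 0.077, 0.09, 0.035, 0.006, 0.002)
_TSTAGE = ("T1a", "T1b", "T2a", "T2b", "T3", "T4")
_TSTAGE_P = (0.35, 0.25, 0.20, 0.07, 0.08, 0.05)
_NSTAGE = ("N0", "N1", "N2")
_NSTAGE_P = (0.80, 0.10, 0.10)
_MSTAGE = ("M0", "M1a")
_MSTAGE_P = (0.99, 0.01)


class SimConfigError(ValueError):
    """Raised when a :class:`SimConfig` is internally inconsistent."""


class PlantedMarker(NamedTuple):
    """A target probe given a true case/control difference.

    ``direction`` is ``"up"`` (higher in cancer) or ``"down"``; ``effect`` is
    the class-mean difference in log2 units.
    """

    probe_id: str
    direction: str
    effect: float


@dataclass(frozen=True)
class CovariateModel:
    """Logistic linkage of age/sex/smoking to case status.

    The linear predictor ``beta_age*(age - age_mean) + beta_male*male +
    beta_smoker*smoker`` weights which members of the simulated population
    end up in the cancer arm, producing the covariate imbalance seen in
    unmatched case/control series.
    """

    age_mean: float = 55.0
    age_sd: float = 10.0
    male_frac: float = 0.5
    smoker_frac: float = 0.35
    beta_age: float = 0.05
    beta_male: float = 0.3
    beta_smoker: float = 0.8


@dataclass(frozen=True)
class SimConfig:
    n_mirnas: int = 500
    n_negctrl_probes: int = 100
    internal_control_ids: tuple[str, str, str] = DEFAULT_CONTROLS
    n_cancer: int = 200
    n_control: int = 200
    planted_markers: tuple[PlantedMarker, ...] = ()
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 1.0
    #: fraction of target probes expressed near chip background (these end up
    #: absent/floored and are removed by the expression filter)
    frac_low_expressed: float = 0.35
    low_log2_mean: float = 3.0
    negctrl_log2_mean: float = 3.0
    negctrl_log2_sd: float = 0.1
    control_log2_mean: float = 10.0
    control_log2_sd: float = 0.1
    #: per-sample technical scale factor (log2 sd) applied to every spot;
    #: internal-control normalization exists to remove exactly this
    sample_scale_log2_sd: float = 0.3
    flag_rate: float = 2.0
    frac_bad_chips: float = 0.044
    covariate_model: CovariateModel = field(default_factory=CovariateModel)
    prior_cancer_rate: float = 0.019
    pretreated_rate: float = 0.011
    missing_info_rate: float = 0.015
    long_interval_rate: float = 0.0024
    ncc_control_frac: float = 0.094
    postop_decay: float = 3.0
    prepost_chip_log2_sd: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_mirnas", "n_negctrl_probes", "n_cancer", "n_control"):
            if getattr(self, name) <= 0:
                raise SimConfigError(f"{name} must be > 0, got {getattr(self, name)}")
        if not 0.0 <= self.frac_bad_chips < 1.0:
            raise SimConfigError(f"frac_bad_chips must be in [0, 1), got {self.frac_bad_chips}")
        if len(self.internal_control_ids) != 3:
            raise SimConfigError("exactly three internal-control ids are required")
        targets = set(self.target_ids())
        ctrl = set(self.internal_control_ids)
        for m in self.planted_markers:
            if not math.isfinite(m.effect):
                raise SimConfigError(f"planted effect for {m.probe_id} is not finite")
            if m.direction not in ("up", "down"):
                raise SimConfigError(f"planted direction must be 'up' or 'down', got {m.direction!r}")
            if m.probe_id not in targets:
                raise SimConfigError(f"planted marker {m.probe_id} is not a target probe")
            if m.probe_id in ctrl:
                raise SimConfigError(f"planted marker {m.probe_id} collides with an internal control")
        if len({m.probe_id for m in self.planted_markers}) != len(self.planted_markers):
            raise SimConfigError("duplicate planted marker probe ids")

    def target_ids(self) -> list[str]:
        return [f"miR-{i:04d}" for i in range(1, self.n_mirnas + 1)]

    def negctrl_ids(self) -> list[str]:
        return [f"NEGCTRL-{i:03d}" for i in range(1, self.n_negctrl_probes + 1)]

    # -- flat YAML round-trip -------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        d = {
            **{k: getattr(self, k) for k in self.__dataclass_fields__
               if k not in ("planted_markers", "covariate_model", "internal_control_ids")},
            "internal_control_ids": list(self.internal_control_ids),
            "planted_markers": [list(m) for m in self.planted_markers],
            "covariate_model": dict(self.covariate_model.__dict__),
        }
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["internal_control_ids"] = tuple(d.get("internal_control_ids", DEFAULT_CONTROLS))
        d["planted_markers"] = tuple(
            PlantedMarker(str(p), str(dr), float(e)) for p, dr, e in d.get("planted_markers", ())
        )
        d["covariate_model"] = CovariateModel(**d.get("covariate_model", {}))
        cfg = cls(**d)
        cfg.validate()
        return cfg


@dataclass
class ChipProfile:
    """One sample's raw probe table, held as parallel numpy arrays."""

    sample_id: str
    probe_id: np.ndarray     # object (str)
    probe_type: np.ndarray   # object (str), values in {target, negative_control, internal_control}
    signal: np.ndarray       # float64, linear intensity, >= 0
    flagged: np.ndarray      # bool

    def __post_init__(self) -> None:
        n = len(self.probe_id)
        if not (len(self.probe_type) == len(self.signal) == len(self.flagged) == n):
            raise ValueError(f"chip {self.sample_id}: column lengths differ")
        if len(set(self.probe_id)) != n:
            raise ValueError(f"chip {self.sample_id}: duplicate probe ids")
        if np.any(self.signal < 0):
            raise ValueError(f"chip {self.sample_id}: negative signal")

    def _of_type(self, probe_type: str) -> np.ndarray:
        return np.asarray(self.probe_type) == probe_type

    @property
    def negctrl_signals(self) -> np.ndarray:
        return self.signal[self._of_type(NEGATIVE_CONTROL)]

    @property
    def negctrl_ids(self) -> np.ndarray:
        return self.probe_id[self._of_type(NEGATIVE_CONTROL)]

    @property
    def target_ids(self) -> np.ndarray:
        return self.probe_id[self._of_type(TARGET)]

    @property
    def target_signals(self) -> np.ndarray:
        return self.signal[self._of_type(TARGET)]

    @property
    def flag_count(self) -> int:
        return int(np.count_nonzero(self.flagged))

    def signal_of(self, probe: str) -> float:
        idx = np.flatnonzero(self.probe_id == probe)
        if idx.size == 0:
            raise KeyError(f"chip {self.sample_id}: no probe {probe!r}")
        return float(self.signal[idx[0]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "probe_id": self.probe_id,
                "probe_type": self.probe_type,
                "signal": self.signal,
                "flagged": self.flagged,
            }
        )

    def equals(self, other: "ChipProfile") -> bool:
        return (
            self.sample_id == other.sample_id
            and list(self.probe_id) == list(other.probe_id)
            and list(self.probe_type) == list(other.probe_type)
            and np.array_equal(self.signal, other.signal)
            and np.array_equal(self.flagged, other.flagged)
        )


@dataclass
class SampleMeta:
    """Clinical covariates and bookkeeping for one serum sample."""

    sample_id: str
    label: str                     # "cancer" | "non_cancer"
    source: str = "NCC_cancer"     # "NCC_cancer" | "NCC_noncancer" | "YMC"
    age: float = 60.0
    sex: str = "M"                 # "M" | "F"
    smoking: str | None = "never"  # "ever" | "never" | None (missing)
    histology: str | None = None
    pstage: str | None = None
    t: str | None = None
    n: str | None = None
    m: str | None = None
    prior_cancer: bool = False
    pretreated: bool = False
    interval_days: int | None = None
    timepoint: str = "pre_op"      # "pre_op" | "post_op"
    pair_id: str | None = None


_META_COLS = list(SampleMeta.__dataclass_fields__)


def metas_to_frame(metas: Sequence[SampleMeta] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(metas, pd.DataFrame):
        return metas.copy()
    return pd.DataFrame([{c: getattr(m, c) for c in _META_COLS} for m in metas])


def frame_to_metas(frame: pd.DataFrame) -> list[SampleMeta]:
    out = []
    for _, row in frame.iterrows():
        kwargs = {}
        for c in _META_COLS:
            v = row.get(c)
            if pd.isna(v):
                v = None
            kwargs[c] = v
        if kwargs["interval_days"] is not None:
            kwargs["interval_days"] = int(kwargs["interval_days"])
        kwargs["age"] = float(kwargs["age"])
        kwargs["prior_cancer"] = bool(kwargs["prior_cancer"])
        kwargs["pretreated"] = bool(kwargs["pretreated"])
        out.append(SampleMeta(**kwargs))
    return out


# ---------------------------------------------------------------------------
# generation internals
# ---------------------------------------------------------------------------


def _draw_covariates(rng: np.random.Generator, n: int, cm: CovariateModel):
    age = rng.normal(cm.age_mean, cm.age_sd, n)
    male = rng.random(n) < cm.male_frac
    smoker = rng.random(n) < cm.smoker_frac
    return age, male, smoker


def _assign_cancer(rng, age, male, smoker, cm: CovariateModel, n_cancer: int) -> np.ndarray:
    """Pick exactly n_cancer samples with probability tilted by the logistic
    linear predictor (Gumbel-max trick: weighted sampling without replacement)."""
    eta = cm.beta_age * (age - cm.age_mean) + cm.beta_male * male + cm.beta_smoker * smoker
    keys = eta + rng.gumbel(size=len(age))
    order = np.argsort(-keys, kind="stable")
    is_cancer = np.zeros(len(age), dtype=bool)
    is_cancer[order[:n_cancer]] = True
    return is_cancer


def _probe_means(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-target baseline log2 means; a fraction sit near chip background."""
    means = np.full(cfg.n_mirnas, cfg.baseline_log2_mean)
    planted = {m.probe_id for m in cfg.planted_markers}
    ids = cfg.target_ids()
    eligible = np.array([i for i, p in enumerate(ids) if p not in planted])
    n_low = int(round(cfg.frac_low_expressed * cfg.n_mirnas))
    n_low = min(n_low, eligible.size)
    if n_low > 0:
        low_idx = rng.choice(eligible, size=n_low, replace=False)
        means[low_idx] = cfg.low_log2_mean
    return means


def _marker_delta(cfg: SimConfig) -> np.ndarray:
    """Signed log2 offset added to cancer samples per target probe."""
    delta = np.zeros(cfg.n_mirnas)
    index = {p: i for i, p in enumerate(cfg.target_ids())}
    for mk in cfg.planted_markers:
        delta[index[mk.probe_id]] = mk.effect if mk.direction == "up" else -mk.effect
    return delta


def _build_chip(cfg, sample_id, target_lin, ctrl_lin, neg_lin, flagged) -> ChipProfile:
    probe_id = np.array(cfg.target_ids() + list(cfg.internal_control_ids) + cfg.negctrl_ids(), dtype=object)
    probe_type = np.array(
        [TARGET] * cfg.n_mirnas + [INTERNAL_CONTROL] * 3 + [NEGATIVE_CONTROL] * cfg.n_negctrl_probes,
        dtype=object,
    )
    signal = np.concatenate([target_lin, ctrl_lin, neg_lin])
    return ChipProfile(sample_id, probe_id, probe_type, signal, flagged)


def _chip_signals(cfg: SimConfig, rng, n: int, target_log2: np.ndarray):
    """Add the per-sample technical scale and draw control/negctrl spots.

    Returns (shift, target_lin, ctrl_lin, neg_log2) with the shift already
    applied; neg_log2 is returned on the log2 scale so QC-failing chips can
    have their spread inflated before exponentiation.
    """
    shift = rng.normal(0.0, cfg.sample_scale_log2_sd, n)
    target_lin = 2.0 ** (target_log2 + shift[:, None])
    ctrl_log2 = cfg.control_log2_mean + shift[:, None] + rng.normal(0.0, cfg.control_log2_sd, (n, 3))
    neg_log2 = (
        cfg.negctrl_log2_mean
        + shift[:, None]
        + rng.normal(0.0, cfg.negctrl_log2_sd, (n, cfg.n_negctrl_probes))
    )
    return shift, target_lin, 2.0 ** ctrl_log2, neg_log2


def _draw_flags(cfg: SimConfig, rng, n: int, n_probes: int):
    counts = rng.poisson(cfg.flag_rate, n)
    flags = np.zeros((n, n_probes), dtype=bool)
    for i in range(n):
        if counts[i] > 0:
            flags[i, rng.choice(n_probes, size=min(counts[i], n_probes), replace=False)] = True
    return flags


def _spoil_chips(cfg: SimConfig, rng, n: int, flags: np.ndarray, neg_log2: np.ndarray, shift: np.ndarray):
    """Engineer floor(frac_bad_chips * n) chips to fail QC deterministically:
    alternating excess flagged spots and inflated negative-control spread."""
    n_bad = int(np.floor(cfg.frac_bad_chips * n))
    if n_bad == 0:
        return
    bad = rng.choice(n, size=n_bad, replace=False)
    n_probes = flags.shape[1]
    for j, i in enumerate(bad):
        if j % 2 == 0:
            extra = 11 + rng.poisson(3)
            flags[i, :] = False
            flags[i, rng.choice(n_probes, size=min(extra, n_probes), replace=False)] = True
        else:
            # log2 sd 0.45 -> linear CV ~0.32, comfortably over the 0.15 rule
            neg_log2[i] = (
                cfg.negctrl_log2_mean + shift[i] + rng.normal(0.0, 0.45, neg_log2.shape[1])
            )


def _cancer_clinical(cfg: SimConfig, rng, meta: SampleMeta) -> None:
    meta.histology = str(rng.choice(_HISTOLOGY, p=_HISTOLOGY_P))
    meta.pstage = str(rng.choice(_PSTAGE, p=_PSTAGE_P))
    meta.t = str(rng.choice(_TSTAGE, p=_TSTAGE_P))
    meta.n = str(rng.choice(_NSTAGE, p=_NSTAGE_P))
    meta.m = str(rng.choice(_MSTAGE, p=_MSTAGE_P))
    meta.prior_cancer = bool(rng.random() < cfg.prior_cancer_rate)
    meta.pretreated = bool(rng.random() < cfg.pretreated_rate)
    if rng.random() < cfg.long_interval_rate:
        meta.interval_days = int(rng.integers(180, 366))
    else:
        meta.interval_days = int(rng.integers(7, 121))
    if rng.random() < cfg.missing_info_rate:
        # missing clinical information: half lose smoking, half lose stage
        if rng.random() < 0.5:
            meta.smoking = None
        else:
            meta.pstage = meta.t = meta.n = meta.m = None


def generate_cohort(config: SimConfig) -> tuple[list[ChipProfile], list[SampleMeta]]:
    """Simulate a case/control serum cohort of raw chips plus metadata.

    Deterministic for a fixed ``config`` (including ``seed``).  Planted
    markers shift the cancer-class mean of their probe by ``effect`` log2
    units in the configured direction; all other target probes are drawn
    identically in both classes.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_cancer + config.n_control
    cm = config.covariate_model

    age, male, smoker = _draw_covariates(rng, n, cm)
    is_cancer = _assign_cancer(rng, age, male, smoker, cm, config.n_cancer)

    means = _probe_means(config, rng)
    delta = _marker_delta(config)
    target_log2 = (
        means[None, :]
        + np.where(is_cancer[:, None], delta[None, :], 0.0)
        + rng.normal(0.0, config.baseline_log2_sd, (n, config.n_mirnas))
    )
    shift, target_lin, ctrl_lin, neg_log2 = _chip_signals(config, rng, n, target_log2)
    n_probes = config.n_mirnas + 3 + config.n_negctrl_probes
    flags = _draw_flags(config, rng, n, n_probes)
    _spoil_chips(config, rng, n, flags, neg_log2, shift)
    neg_lin = 2.0 ** neg_log2

    chips: list[ChipProfile] = []
    metas: list[SampleMeta] = []
    for i in range(n):
        sid = f"S{i + 1:04d}"
        chips.append(_build_chip(config, sid, target_lin[i], ctrl_lin[i], neg_lin[i], flags[i]))
        if is_cancer[i]:
            meta = SampleMeta(
                sid, "cancer", "NCC_cancer", float(age[i]),
                "M" if male[i] else "F", "ever" if smoker[i] else "never",
            )
            _cancer_clinical(config, rng, meta)
        else:
            src = "NCC_noncancer" if rng.random() < config.ncc_control_frac else "YMC"
            meta = SampleMeta(
                sid, "non_cancer", src, float(age[i]),
                "M" if male[i] else "F", "ever" if smoker[i] else "never",
            )
        metas.append(meta)
    return chips, metas


def generate_prepost(config: SimConfig, n_pairs: int) -> tuple[list[ChipProfile], list[SampleMeta]]:
    """Paired pre-/post-resection chips for ``n_pairs`` cancer patients.

    Each pair shares a patient-level expression profile; the two chips add
    independent measurement noise (``prepost_chip_log2_sd``).  After surgery
    each planted marker moves ``postop_decay`` log2 units back toward the
    non-cancer baseline (up-markers fall, down-markers rise), so diagnostic
    indexes built on the markers decrease post-operatively.
    """
    config.validate()
    if n_pairs <= 0:
        raise SimConfigError(f"n_pairs must be > 0, got {n_pairs}")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1031]))
    cm = config.covariate_model

    age, male, smoker = _draw_covariates(rng, n_pairs, cm)
    means = _probe_means(config, rng)
    delta = _marker_delta(config)
    patient = means[None, :] + delta[None, :] + rng.normal(
        0.0, config.baseline_log2_sd, (n_pairs, config.n_mirnas)
    )
    decay = np.sign(delta) * config.postop_decay  # toward baseline; zero off-marker

    chips: list[ChipProfile] = []
    metas: list[SampleMeta] = []
    n_probes = config.n_mirnas + 3 + config.n_negctrl_probes
    for phase, offset in (("pre_op", 0.0), ("post_op", -1.0)):
        target_log2 = patient + offset * decay[None, :] + rng.normal(
            0.0, config.prepost_chip_log2_sd, (n_pairs, config.n_mirnas)
        )
        shift, target_lin, ctrl_lin, neg_log2 = _chip_signals(config, rng, n_pairs, target_log2)
        flags = _draw_flags(config, rng, n_pairs, n_probes)
        neg_lin = 2.0 ** neg_log2
        for i in range(n_pairs):
            pair = f"P{i + 1:04d}"
            sid = f"{pair}-{'pre' if phase == 'pre_op' else 'post'}"
            chips.append(_build_chip(config, sid, target_lin[i], ctrl_lin[i], neg_lin[i], flags[i]))
            meta = SampleMeta(
                sid, "cancer", "NCC_cancer", float(age[i]),
                "M" if male[i] else "F", "ever" if smoker[i] else "never",
                timepoint=phase, pair_id=pair,
            )
            _cancer_clinical(config, rng, meta)
            meta.interval_days = int(rng.integers(7, 121))
            metas.append(meta)
    return chips, metas


# ---------------------------------------------------------------------------
# fixture I/O
# ---------------------------------------------------------------------------


def write_fixtures(
    chips: Sequence[ChipProfile], metas: Sequence[SampleMeta] | pd.DataFrame, directory: str | Path
) -> list[Path]:
    """Write one chip TSV per sample plus ``metadata.csv``.

    The dialects round-trip losslessly through :func:`mirpanel.preprocess.read_chip_tsv`
    and :func:`mirpanel.preprocess.read_metadata_csv`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if len(chips) == 0:
        logger.warning("write_fixtures called with no chips; writing metadata only")
    for chip in chips:
        path = directory / f"{chip.sample_id}.tsv"
        try:
            # %.17g guarantees exact float64 round-trip through the TSV
            chip.to_frame().to_csv(
                path, sep="\t", index=False, lineterminator="\n", float_format="%.17g"
            )
        except OSError as exc:
            raise OSError(f"failed writing chip table {path}: {exc}") from exc
        written.append(path)
    meta_path = directory / "metadata.csv"
    try:
        metas_to_frame(metas).to_csv(meta_path, index=False, lineterminator="\n")
    except OSError as exc:
        raise OSError(f"failed writing metadata {meta_path}: {exc}") from exc
    written.append(meta_path)
    return written


def with_markers(config: SimConfig, markers: Sequence[tuple[str, str, float]]) -> SimConfig:
    """Convenience: return a copy of ``config`` with planted markers set."""
    return replace(config, planted_markers=tuple(PlantedMarker(*m) for m in markers))
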