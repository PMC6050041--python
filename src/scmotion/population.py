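"""Ground-truth neuron populations for the synthetic-recording generator.

Each simulated neuron carries the generative parameters the downstream analysis
tries to recover: a von Mises direction tuning curve, an affine center-surround
modulation law R_CS = a(dtheta) * R_C + b(dtheta), feature-contrast gain
factors, a 2D Gaussian receptive field, indicator kinetics, and noise.

Default parameters encode the superficial-SGS study conditions: the excitatory
modulation law is anchored at the measured population slopes/intercepts
(a, b) = (0.50, 0.48), (1.17, 2.54), (1.63, 1.55) %dF/F0 at direction
differences 0/90/180 degrees (slopes at 45/135 linearly interpolated), and the
inhibitory law is suppressive at every direction difference, most strongly for
the opposite surround.  A ``depth_survey`` preset adds linear depth gradients
for the deep-imaging (nuclear indicator) conditions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigValidationError, InvalidParameterError

DELTA_THETAS = (0, 45, 90, 135, 180)
FEATURE_TAGS = ("anti_phase", "tf_low", "tf_high", "static_iso", "static_mid", "static_cross")
CELL_CLASSES = ("excitatory", "inhibitory")
RESPONSE_TYPES = ("center_responsive", "center_silent", "silent")


def _interp_law(anchors: dict[int, float]) -> dict[int, float]:
    """Fill direction differences 45 and 135 by linear interpolation of the
    0/90/180 anchors."""
    full = dict(anchors)
    full[45] = 0.5 * (anchors[0] + anchors[90])
    full[135] = 0.5 * (anchors[90] + anchors[180])
    return {d: full[d] for d in DELTA_THETAS}


@dataclass
class ClassParams:
    """Per-cell-class generative parameters.

    Slopes are dimensionless; intercepts are in % dF/F0 (converted to
    fractional units when the law is materialized).  ``a180_kappa_coupling``
    (and ``a0_kappa_coupling``) tilt the per-cell slope with the cell's tuning
    concentration (standardized log kappa), producing the selectivity-modulation
    correlations seen across the population; the perturbations are zero-mean so
    class-average laws stay at the anchors.
    """

    slopes: dict[int, float] = field(default_factory=dict)
    intercepts_pct: dict[int, float] = field(default_factory=dict)
    slope_jitter_sd: float = 0.08
    intercept_jitter_pct_sd: float = 0.25
    a180_kappa_coupling: float = 0.0
    a0_kappa_coupling: float = 0.0
    # fractions of cells by response type (center_responsive, center_silent, silent)
    response_fractions: tuple[float, float, float] = (0.44, 0.235, 0.325)
    # log-normal tuning concentration: kappa = exp(N(log_kappa_mu, log_kappa_sigma));
    # a second component (weight kappa_mix_weight) models a distinct high/low
    # selectivity cluster where present.
    log_kappa_mu: float = 0.0
    log_kappa_sigma: float = 1.0
    log_kappa_mu2: float | None = None
    log_kappa_sigma2: float | None = None
    kappa_mix_weight: float = 0.0
    # peak center response, fractional dF/F0, log-normal
    peak_median: float = 0.6
    peak_log_sigma: float = 0.5
    surround_alone_prob: float = 0.0
    surround_gain: float = 0.5
    # emergent center-silent response: amplitude and direction-difference profile
    emergent_median: float = 0.4
    emergent_log_sigma: float = 0.5
    emergent_profile: dict[int, float] = field(
        default_factory=lambda: {0: 0.05, 45: 0.15, 90: 0.35, 135: 0.6, 180: 1.0}
    )
    feature_factors: dict[str, float] = field(default_factory=dict)
    static_gain: float = 0.5
    rf_scatter_sd_deg: float = 3.0
    rf_sigma_deg: float = 4.0
    rf_gain: float = 0.8


def _excitatory_defaults() -> ClassParams:
    return ClassParams(
        slopes=_interp_law({0: 0.50, 90: 1.17, 180: 1.63}),
        intercepts_pct=_interp_law({0: 0.48, 90: 2.54, 180: 1.55}),
        a180_kappa_coupling=0.22,
        response_fractions=(0.438, 0.236, 0.326),
        log_kappa_mu=0.0,
        log_kappa_sigma=1.0,
        surround_alone_prob=0.03,
        feature_factors={
            "anti_phase": 0.95,
            "tf_low": 0.90,
            "tf_high": 0.90,
            "static_iso": 0.55,
            "static_mid": 0.65,
            "static_cross": 0.75,
        },
        rf_scatter_sd_deg=3.0,
    )


def _inhibitory_defaults() -> ClassParams:
    return ClassParams(
        slopes=_interp_law({0: 0.75, 90: 0.55, 180: 0.35}),
        intercepts_pct=_interp_law({0: 0.30, 90: 0.30, 180: 0.30}),
        a180_kappa_coupling=-0.10,
        a0_kappa_coupling=0.08,
        response_fractions=(0.581, 0.130, 0.289),
        # two selectivity clusters (broadly and sharply tuned)
        log_kappa_mu=float(np.log(0.35)),
        log_kappa_sigma=0.5,
        log_kappa_mu2=float(np.log(2.2)),
        log_kappa_sigma2=0.4,
        kappa_mix_weight=0.45,
        peak_median=0.5,
        surround_alone_prob=0.538,
        emergent_median=0.25,
        feature_factors={
            "anti_phase": 0.80,
            "tf_low": 0.75,
            "tf_high": 0.75,
            "static_iso": 0.65,
            "static_mid": 0.72,
            "static_cross": 0.80,
        },
        rf_scatter_sd_deg=4.5,
    )


@dataclass
class GeneratorConfig:
    """Population-level generator configuration.

    ``depth_gradient`` switches on linear declines of tuning concentration and
    of the excitatory opposite-surround slope with imaging depth (the
    deep-imaging study conditions); the default (superficial, fast indicator)
    leaves both flat so the class anchors hold for the whole population.
    """

    excitatory_fraction: float = 0.554
    depth_range_um: tuple[float, float] = (10.0, 45.0)
    depth_gradient: bool = False
    kappa_decline_per_um: float = 0.004   # fractional kappa loss per um depth
    a180_decline_per_um: float = 0.0065   # excitatory opposite-surround slope loss per um
    indicator: str = "fast"
    noise_sd: float = 0.10                # per-frame trace noise, dF/F0 units
    baseline_F_median: float = 100.0
    baseline_F_log_sigma: float = 0.3
    unmappable_rf_prob: float = 0.194     # center-silent cells lacking a mappable RF
    cells_per_fov: int = 60
    excitatory: ClassParams = field(default_factory=_excitatory_defaults)
    inhibitory: ClassParams = field(default_factory=_inhibitory_defaults)

    def __post_init__(self) -> None:
        errors = []
        if not 0.0 <= self.excitatory_fraction <= 1.0:
            errors.append("excitatory_fraction")
        if self.depth_range_um[0] < 0 or self.depth_range_um[1] < self.depth_range_um[0]:
            errors.append("depth_range_um")
        if self.indicator not in ("fast", "slow_nuclear"):
            errors.append("indicator")
        if self.noise_sd < 0:
            errors.append("noise_sd")
        for name in ("excitatory", "inhibitory"):
            cp: ClassParams = getattr(self, name)
            if abs(sum(cp.response_fractions) - 1.0) > 1e-6:
                errors.append(f"{name}.response_fractions")
            if set(cp.slopes) != set(DELTA_THETAS) or set(cp.intercepts_pct) != set(DELTA_THETAS):
                errors.append(f"{name}.slopes/intercepts_pct")
            if any(a < 0 for a in cp.slopes.values()):
                errors.append(f"{name}.slopes")
        if errors:
            raise ConfigValidationError(f"invalid config values for keys: {', '.join(errors)}")

    @classmethod
    def from_dict(cls, data: dict) -> "GeneratorConfig":
        """Build a config from nested dicts, rejecting unknown keys."""
        data = dict(data)
        bad = [k for k in data if k not in {f.name for f in dataclasses.fields(cls)}]
        if bad:
            raise ConfigValidationError(f"unknown config keys: {', '.join(sorted(bad))}")
        for name in ("excitatory", "inhibitory"):
            if name in data and isinstance(data[name], dict):
                sub = dict(data[name])
                known = {f.name for f in dataclasses.fields(ClassParams)}
                bad = [k for k in sub if k not in known]
                if bad:
                    raise ConfigValidationError(
                        f"unknown config keys: {', '.join(f'{name}.{k}' for k in sorted(bad))}"
                    )
                for law_key in ("slopes", "intercepts_pct", "emergent_profile"):
                    if law_key in sub:
                        sub[law_key] = {int(k): float(v) for k, v in sub[law_key].items()}
                base = _excitatory_defaults() if name == "excitatory" else _inhibitory_defaults()
                data[name] = dataclasses.replace(base, **sub)
        if "depth_range_um" in data:
            data["depth_range_um"] = tuple(data["depth_range_um"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["depth_range_um"] = list(self.depth_range_um)
        for name in ("excitatory", "inhibitory"):
            d[name]["response_fractions"] = list(d[name]["response_fractions"])
        return d


def depth_survey_config() -> GeneratorConfig:
    """Deep-imaging preset: slow nuclear indicator, depths spanning 10-205 um,
    linear depth gradients of selectivity and opposite-surround potentiation."""
    cfg = GeneratorConfig(
        depth_range_um=(10.0, 205.0),
        depth_gradient=True,
        indicator="slow_nuclear",
    )
    return cfg


def excitatory_recovery_config() -> GeneratorConfig:
    """All-excitatory, all-center-responsive preset used for parameter-recovery
    runs of the population modulation law."""
    cfg = GeneratorConfig(excitatory_fraction=1.0)
    cfg.excitatory.response_fractions = (1.0, 0.0, 0.0)
    return cfg


@dataclass
class CellGroundTruth:
    """Generative parameters of one simulated neuron."""

    cell_class: str
    depth_um: float
    preferred_direction: float
    tuning_concentration: float
    peak_response: float
    center_silent: bool
    surround_alone_responsive: bool
    modulation_law: dict[int, tuple[float, float]]  # dtheta -> (a, b fractional)
    feature_contrast_factors: dict[str, float]
    rf_centroid: tuple[float, float]
    rf_sigma_deg: float
    baseline_F: float
    noise_sd: float
    indicator: str
    surround_gain: float = 0.5
    static_gain: float = 0.5
    rf_gain: float = 0.8
    has_mappable_rf: bool = True
    fov_id: int = 0

    def __post_init__(self) -> None:
        if self.peak_response < 0 or self.tuning_concentration < 0:
            raise InvalidParameterError("peak_response and tuning_concentration must be >= 0")
        if set(self.modulation_law) != set(DELTA_THETAS):
            raise InvalidParameterError("modulation_law must cover direction differences 0..180")

    @property
    def responsive(self) -> bool:
        """True if the cell responds to anything (center, surround, or a C-S pair)."""
        if self.peak_response > 0 or self.surround_alone_responsive:
            return True
        return any(b > 0 for _, b in self.modulation_law.values())


def _log_kappa_moments(cp: ClassParams) -> tuple[float, float]:
    """Mean and SD of log kappa under the (possibly mixed) sampling law, used
    to standardize the selectivity-coupling term so it stays zero-mean."""
    if cp.kappa_mix_weight > 0 and cp.log_kappa_mu2 is not None:
        w = cp.kappa_mix_weight
        mu1, s1 = cp.log_kappa_mu, cp.log_kappa_sigma
        mu2 = cp.log_kappa_mu2
        s2 = cp.log_kappa_sigma2 or cp.log_kappa_sigma
        mean = (1 - w) * mu1 + w * mu2
        var = (1 - w) * (s1**2 + mu1**2) + w * (s2**2 + mu2**2) - mean**2
        return mean, float(np.sqrt(max(var, 1e-12)))
    return cp.log_kappa_mu, max(cp.log_kappa_sigma, 1e-6)


def _sample_kappa(cp: ClassParams, n: int, rng: np.random.Generator) -> np.ndarray:
    kappa1 = np.exp(rng.normal(cp.log_kappa_mu, cp.log_kappa_sigma, n))
    if cp.kappa_mix_weight > 0 and cp.log_kappa_mu2 is not None:
        kappa2 = np.exp(rng.normal(cp.log_kappa_mu2, cp.log_kappa_sigma2 or cp.log_kappa_sigma, n))
        use2 = rng.random(n) < cp.kappa_mix_weight
        kappa1 = np.where(use2, kappa2, kappa1)
    return kappa1


def sample_population(
    config: GeneratorConfig | dict, n_cells: int, seed: int = 0
) -> list[CellGroundTruth]:
    """Draw a deterministic ground-truth population.

    Cell class, response type, depth, tuning, modulation law, receptive field,
    and noise parameters are sampled independently per cell; all randomness
    flows from ``seed``.
    """
    if isinstance(config, dict):
        config = GeneratorConfig.from_dict(config)
    if n_cells < 1:
        raise InvalidParameterError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    cells: list[CellGroundTruth] = []
    is_exc = rng.random(n_cells) < config.excitatory_fraction
    depths = rng.uniform(*config.depth_range_um, n_cells)
    for i in range(n_cells):
        cls = "excitatory" if is_exc[i] else "inhibitory"
        cp: ClassParams = getattr(config, cls)
        depth = float(depths[i])
        rtype = rng.choice(RESPONSE_TYPES, p=np.asarray(cp.response_fractions))

        kappa = float(_sample_kappa(cp, 1, rng)[0])
        if config.depth_gradient:
            kappa *= max(0.15, 1.0 - config.kappa_decline_per_um * depth)
        # standardized log-kappa drives selectivity-modulation coupling
        z_mu, z_sd = _log_kappa_moments(cp)
        z_kappa = float(np.clip((np.log(kappa) - z_mu) / z_sd, -2.0, 2.0))

        pref = float(rng.choice(np.arange(0.0, 360.0, 45.0)))
        peak = float(cp.peak_median * np.exp(rng.normal(0.0, cp.peak_log_sigma)))

        a0 = cp.slopes[0] + rng.normal(0.0, cp.slope_jitter_sd) + cp.a0_kappa_coupling * z_kappa
        a90 = cp.slopes[90] + rng.normal(0.0, cp.slope_jitter_sd)
        a180 = cp.slopes[180] + rng.normal(0.0, cp.slope_jitter_sd) + cp.a180_kappa_coupling * z_kappa
        if cls == "excitatory" and config.depth_gradient:
            a180 -= config.a180_decline_per_um * depth
        if cls == "inhibitory":
            a0, a90, a180 = (float(np.clip(a, 0.02, 0.98)) for a in (a0, a90, a180))
        else:
            a0, a90, a180 = (float(max(a, 0.0)) for a in (a0, a90, a180))
        slopes = {0: a0, 45: 0.5 * (a0 + a90), 90: a90, 135: 0.5 * (a90 + a180), 180: a180}

        intercepts = {
            d: float(max(cp.intercepts_pct[d] / 100.0 + rng.normal(0.0, cp.intercept_jitter_pct_sd / 100.0), 0.0))
            for d in DELTA_THETAS
        }

        center_silent = rtype == "center_silent"
        silent = rtype == "silent"
        if center_silent:
            amp = float(cp.emergent_median * np.exp(rng.normal(0.0, cp.emergent_log_sigma)))
            law = {d: (0.0, amp * cp.emergent_profile[d]) for d in DELTA_THETAS}
            peak = 0.0
        elif silent:
            law = {d: (0.0, 0.0) for d in DELTA_THETAS}
            peak = 0.0
        else:
            law = {d: (slopes[d], intercepts[d]) for d in DELTA_THETAS}

        surround_alone = (not silent) and (not center_silent) and (rng.random() < cp.surround_alone_prob)

        fov = i // max(config.cells_per_fov, 1)
        centroid = tuple(rng.normal(0.0, cp.rf_scatter_sd_deg, 2).round(3))
        has_rf = True
        if center_silent or silent:
            has_rf = rng.random() >= config.unmappable_rf_prob

        cells.append(
            CellGroundTruth(
                cell_class=cls,
                depth_um=depth,
                preferred_direction=pref,
                tuning_concentration=kappa,
                peak_response=peak,
                center_silent=center_silent,
                surround_alone_responsive=surround_alone,
                modulation_law=law,
                feature_contrast_factors=dict(cp.feature_factors),
                rf_centroid=(float(centroid[0]), float(centroid[1])),
                rf_sigma_deg=float(cp.rf_sigma_deg),
                baseline_F=float(config.baseline_F_median * np.exp(rng.normal(0.0, config.baseline_F_log_sigma))),
                noise_sd=float(config.noise_sd),
                indicator=config.indicator,
                surround_gain=cp.surround_gain,
                static_gain=cp.static_gain,
                rf_gain=cp.rf_gain,
                has_mappable_rf=has_rf,
                fov_id=fov,
            )
        )
    return cells
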