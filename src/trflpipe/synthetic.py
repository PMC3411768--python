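"""Synthetic electropherogram and operational-series generator.

The raw fingerprints behind the study design this package targets were never
deposited, so every downstream stage is exercised on simulated data with the
same statistical structure: monthly T-RFLP peak tables for two activated
sludge plants digested with three enzymes, a low-amplitude noise floor under
a few dozen dominant real peaks, sub-bp between-gel size-call jitter, plant
richness scaling with reactor flow as ``S = c * A**z``, one temporally
stable and one erratic community, and monthly operational series with a
controllable influent-to-effluent BOD correlation.

Community abundances follow a log-normal ranked-abundance model whose spread
is parameterized by an *evenness* knob; month-to-month drift replaces a
fraction ``turnover`` of taxa and multiplies abundances by log-normal noise.
The noise floor uses half-normal peak heights: the downstream
median-plus-3-sigma threshold rule presumes near-Gaussian baseline noise,
and a half-normal floor is the matching one-sided model (an exponential
floor is available via ``noise_model`` for heavier-tailed baselines).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import reference

DEFAULT_ENZYMES = ("HaeIII", "RsaI", "MspI")

#: Minimum spacing (bp) enforced between canonical fragment sizes so that
#: jittered peaks remain attributable to their source taxon by a 2 bp binner.
MIN_SIZE_GAP = 3.0


@dataclass
class PlantSpec:
    """Parameters of one simulated plant community.

    ``flow_A`` is the average daily flow (MLD) playing the role of habitat
    size ``A`` in the species-flow power law ``S = c * A**z``; the implied
    richness ``round(c * A**z)`` is the number of true taxa simulated.
    ``evenness`` in (0, 1] shapes the log-normal ranked abundances (1 =
    perfectly even); ``turnover`` in [0, 1] is the fraction of taxa replaced
    each month (0 = temporally frozen community).
    """

    name: str
    flow_A: float
    c_const: float
    z_exp: float
    evenness: float = 0.6
    turnover: float = 0.1
    operational_means: dict = field(default_factory=dict)
    operational_sds: dict = field(default_factory=dict)
    bod_inf_eff_corr: float = 0.0
    abundance_noise_sd: float = 0.25

    def __post_init__(self) -> None:
        if self.flow_A <= 0:
            raise ValueError("flow_A must be positive")
        if not 0 < self.evenness <= 1:
            raise ValueError("evenness must lie in (0, 1]")
        if not 0 <= self.turnover <= 1:
            raise ValueError("turnover must lie in [0, 1]")
        if not -1 <= self.bod_inf_eff_corr <= 1:
            raise ValueError("bod_inf_eff_corr must lie in [-1, 1]")
        if self.richness < 2:
            raise ValueError(
                f"plant {self.name!r}: implied richness c*A**z = "
                f"{self.c_const * self.flow_A ** self.z_exp:.2f} is below 2"
            )

    @property
    def richness(self) -> int:
        """Number of true taxa, S = round(c * A**z)."""
        return int(round(self.c_const * self.flow_A ** self.z_exp))


def default_plants() -> list[PlantSpec]:
    """The two default plant specifications (study conditions).

    Flow, operational means/sds and the influent-effluent BOD correlations
    come from the published plant summaries; per-plant ``c`` is chosen so the
    implied richness matches each plant's reported study-average OTU richness
    at exponent z = 0.359.  The larger plant is stable and even, the smaller
    erratic and dominance-prone.
    """
    z = reference.SPECIES_FLOW_Z
    plants = []
    for name, flow, evenness, turnover in (
        ("HC", 41.20, 0.7, 0.05),
        ("LC", 1.88, 0.5, 0.25),
    ):
        c = reference.AVERAGE_RICHNESS[name] / flow ** z
        plants.append(
            PlantSpec(
                name=name,
                flow_A=flow,
                c_const=c,
                z_exp=z,
                evenness=evenness,
                turnover=turnover,
                operational_means=dict(reference.OPERATIONAL_MEANS[name]),
                operational_sds=dict(reference.OPERATIONAL_SDS[name]),
                bod_inf_eff_corr=reference.BOD_IN_OUT_CORRELATION[name],
            )
        )
    return plants


@dataclass
class SimulationConfig:
    """Full specification of one synthetic study."""

    n_months: int = 12
    plants: list[PlantSpec] = field(default_factory=default_plants)
    enzymes: tuple = DEFAULT_ENZYMES
    size_range: tuple = (50.0, 700.0)
    noise_peaks_per_profile: int = 300
    noise_height_scale: float = 40.0
    signal_to_noise: float = 10.0
    size_jitter_sd: float = 0.15
    noise_model: str = "halfnormal"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_months < 2:
            raise ValueError("n_months must be at least 2")
        lo, hi = self.size_range
        if not lo < hi:
            raise ValueError("size_range min must be below max")
        for value, name in (
            (self.noise_height_scale, "noise_height_scale"),
            (self.signal_to_noise, "signal_to_noise"),
        ):
            if value <= 0:
                raise ValueError(f"{name} must be positive")
        if self.size_jitter_sd < 0:
            raise ValueError("size_jitter_sd must be non-negative")
        if self.noise_model not in ("halfnormal", "exponential"):
            raise ValueError("noise_model must be 'halfnormal' or 'exponential'")
        max_s = max(p.richness for p in self.plants)
        capacity = int((hi - lo) / MIN_SIZE_GAP)
        if max_s > capacity:
            raise ValueError(
                f"richness {max_s} cannot be placed in [{lo}, {hi}] bp at "
                f"{MIN_SIZE_GAP} bp spacing ({capacity} representable bins)"
            )
        self.plants = [
            p if isinstance(p, PlantSpec) else PlantSpec(**p) for p in self.plants
        ]

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["enzymes"] = list(self.enzymes)
        data["size_range"] = list(self.size_range)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        data["plants"] = [PlantSpec(**p) for p in data.get("plants", [])]
        data["enzymes"] = tuple(data.get("enzymes", DEFAULT_ENZYMES))
        data["size_range"] = tuple(data.get("size_range", (50.0, 700.0)))
        return cls(**data)


def _draw_sizes(rng: np.random.Generator, n: int, lo: float, hi: float,
                occupied: np.ndarray | None = None) -> np.ndarray:
    """Draw n canonical fragment sizes >= MIN_SIZE_GAP apart (and apart from
    any already-occupied sizes)."""
    sizes: list[float] = [] if occupied is None else list(occupied)
    out: list[float] = []
    attempts = 0
    while len(out) < n:
        cand = rng.uniform(lo, hi)
        if all(abs(cand - s) >= MIN_SIZE_GAP for s in sizes):
            sizes.append(cand)
            out.append(cand)
        attempts += 1
        if attempts > 200 * n + 1000:
            raise ValueError("could not place canonical fragment sizes without collisions")
    return np.array(out)


def _lognormal_sigma(evenness: float) -> float:
    # evenness 1 -> all taxa equal; smaller evenness -> broader dominance.
    return 2.0 * (1.0 - evenness)


def _simulate_plant_enzyme(rng, cfg: SimulationConfig, plant: PlantSpec, enzyme: str):
    """Yield per-month (true_sizes, heights) for one plant x enzyme series."""
    lo, hi = cfg.size_range
    s = plant.richness
    sigma = _lognormal_sigma(plant.evenness)
    floor = cfg.signal_to_noise * cfg.noise_height_scale

    sizes = _draw_sizes(rng, s, lo, hi)
    # Base heights are bounded below by `floor` so every true peak clears the
    # noise band by the configured signal-to-noise factor.
    base = floor * (1.0 + rng.lognormal(0.0, sigma, s))
    for month in range(cfg.n_months):
        if month > 0 and plant.turnover > 0:
            n_replace = int(round(plant.turnover * s))
            if n_replace:
                idx = rng.choice(s, size=n_replace, replace=False)
                keep_mask = np.ones(s, bool)
                keep_mask[idx] = False
                new_sizes = _draw_sizes(rng, n_replace, lo, hi, occupied=sizes[keep_mask])
                sizes = sizes.copy()
                sizes[idx] = new_sizes
                base = base.copy()
                base[idx] = floor * (1.0 + rng.lognormal(0.0, sigma, n_replace))
        heights = base * np.exp(rng.normal(0.0, plant.abundance_noise_sd, s))
        yield month, sizes.copy(), heights


def simulate_peak_tables(config: SimulationConfig, with_truth: bool = False):
    """Generate the long-form peak table for a full synthetic study.

    For every plant x month x enzyme profile the table holds the plant's
    true community peaks plus ``noise_peaks_per_profile`` baseline peaks at
    uniform positions; every size call is jittered by
    ``N(0, size_jitter_sd)``.  Deterministic under a fixed config seed.

    Parameters
    ----------
    config : SimulationConfig
    with_truth : bool
        If True, also return a copy carrying ``is_signal`` (bool) and
        ``true_size`` (un-jittered bp, NaN for noise) columns for use as
        ground truth in evaluations.

    Returns
    -------
    pandas.DataFrame  (or a (table, truth) pair when ``with_truth``)
    """
    ss = np.random.SeedSequence(config.seed)
    peaks_ss, _ = ss.spawn(2)
    rng = np.random.default_rng(peaks_ss)
    lo, hi = config.size_range

    rows = []
    for plant in config.plants:
        for enzyme in config.enzymes:
            for month, sizes, heights in _simulate_plant_enzyme(rng, config, plant, enzyme):
                sample_id = f"{plant.name}_M{month + 1:02d}"
                n_noise = config.noise_peaks_per_profile
                noise_sizes = rng.uniform(lo, hi, n_noise)
                if config.noise_model == "halfnormal":
                    noise_heights = np.abs(rng.normal(0.0, config.noise_height_scale, n_noise))
                else:
                    noise_heights = rng.exponential(config.noise_height_scale, n_noise)
                all_true = np.concatenate([sizes, noise_sizes])
                all_heights = np.concatenate([heights, noise_heights])
                is_signal = np.zeros(len(all_true), bool)
                is_signal[: len(sizes)] = True
                observed = all_true + rng.normal(0.0, config.size_jitter_sd, len(all_true))
                observed = np.clip(observed, 1e-3, None)
                for t, o, h, sig in zip(all_true, observed, all_heights, is_signal):
                    rows.append((sample_id, plant.name, month + 1, enzyme,
                                 float(o), float(h), bool(sig), float(t)))

    table = pd.DataFrame(
        rows,
        columns=["sample_id", "plant", "month", "enzyme",
                 "size_bp", "height", "is_signal", "true_size"],
    )
    # Jittered floats virtually never collide; enforce key uniqueness anyway.
    dup = table.duplicated(["sample_id", "enzyme", "size_bp"])
    if dup.any():
        table.loc[dup, "size_bp"] += 1e-6
    public = table.drop(columns=["is_signal", "true_size"])
    if with_truth:
        return public, table
    return public


def simulate_operational_table(config: SimulationConfig) -> pd.DataFrame:
    """Generate monthly operational parameters for every plant.

    Each parameter is drawn independently as ``N(mean, sd)`` from the plant's
    stated location/scale (concentrations truncated at zero).  Effluent BOD
    is then rebuilt as a linear blend of the standardized influent BOD and
    independent noise so that the influent-effluent Pearson correlation
    approaches ``bod_inf_eff_corr`` as the number of months grows.
    """
    ss = np.random.SeedSequence(config.seed)
    _, ops_ss = ss.spawn(2)
    rng = np.random.default_rng(ops_ss)

    nonneg = {"bod_in", "bod_out", "tss_in", "tss_out", "adf", "hrt",
              "srt", "fm", "po4", "no3"}
    rows = []
    for plant in config.plants:
        means, sds = plant.operational_means, plant.operational_sds
        n = config.n_months
        draws = {
            key: rng.normal(means[key], sds[key], n) for key in means
        }
        rho = plant.bod_inf_eff_corr
        if sds.get("bod_in", 0) > 0:
            z_in = (draws["bod_in"] - means["bod_in"]) / sds["bod_in"]
        else:
            z_in = np.zeros(n)
        z_eps = rng.normal(0.0, 1.0, n)
        draws["bod_out"] = means["bod_out"] + sds["bod_out"] * (
            rho * z_in + np.sqrt(max(0.0, 1.0 - rho ** 2)) * z_eps
        )
        for key in draws:
            if key in nonneg:
                # influent concentrations are floored at a 1 mg/L detection
                # limit (they are never truly zero); everything else at 0
                floor = 1.0 if key in ("bod_in", "tss_in") else 0.0
                draws[key] = np.clip(draws[key], floor, None)
        for month in range(n):
            row = {"plant": plant.name, "month": month + 1}
            row.update({key: float(draws[key][month]) for key in sorted(draws)})
            rows.append(row)
    return pd.DataFrame(rows)


def simulate_species_flow(
    c: float,
    z: float,
    flows,
    samples_per_flow: int = 2,
    sigma_log10: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-sample (flow, richness) points obeying ``S = c * A**z``.

    ``log10 S`` is ``log10 c + z log10 A`` plus ``N(0, sigma_log10)`` noise,
    rounded to an integer richness (floored at 2) - the sampling model under
    which a log-log least-squares fit is exactly specified.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for a in np.asarray(flows, dtype=float):
        for _ in range(samples_per_flow):
            log_s = np.log10(c) + z * np.log10(a) + rng.normal(0.0, sigma_log10)
            rows.append((float(a), max(2, int(round(10 ** log_s)))))
    return pd.DataFrame(rows, columns=["flow", "richness"])


def simulate_gradient_community(
    n_samples: int = 20,
    n_species: int = 15,
    gradient_sd: float = 1.0,
    niche_width: float = 0.8,
    noise_sd: float = 0.02,
    n_noise_vars: int = 0,
    seed: int = 0,
):
    """Community with unimodal species responses along one known gradient.

    Species optima are spread over the gradient range; sample abundances are
    Gaussian response curves plus truncated noise.  Returns ``(y, x)`` where
    ``x`` holds the structuring gradient (plus optional independent noise
    columns), for validating constrained ordination against ground truth.
    """
    rng = np.random.default_rng(seed)
    grad = np.sort(rng.normal(0.0, gradient_sd, n_samples))
    optima = np.linspace(grad.min(), grad.max(), n_species)
    y = np.exp(-((grad[:, None] - optima[None, :]) ** 2) / (2 * niche_width ** 2))
    y = np.clip(y + rng.normal(0.0, noise_sd, y.shape), 0.0, None)
    samples = [f"s{i + 1:02d}" for i in range(n_samples)]
    ydf = pd.DataFrame(y, index=samples,
                       columns=[f"sp{j + 1:02d}" for j in range(n_species)])
    xcols = {"gradient": grad}
    for k in range(n_noise_vars):
        xcols[f"noise{k + 1}"] = rng.normal(0.0, 1.0, n_samples)
    xdf = pd.DataFrame(xcols, index=samples)
    return ydf, xdf
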