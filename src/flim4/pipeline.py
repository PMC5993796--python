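"""End-to-end orchestration: simulate -> fit -> decompose -> report.

Reproduces the pharmacological stress-test comparisons as direction-checked
tables: each scenario is simulated as a batch of independent images, every
image runs through the full analysis (binning, bi-exponential fitting, QC,
four-Gaussian decomposition, MCR / free-to-bound / redox), and treated
conditions are compared against the control with Welch's t-test.  The
trend of oxidative activity against 1/MCR is checked by linear regression
using each scenario's declared oxidative-activity proxy (a stand-in for
flux-analyzer respirometry, which the simulator does not model).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .components import (
    MetricsReport,
    component_intensities,
    fit_gaussians,
    free_to_bound,
    lifetime_histogram,
    mcr,
    redox_image,
)
from .decay import fit_image
from .meta import AcquisitionMeta, gaussian_irf
from .synth import (
    ScenarioConfig,
    apply_scenario,
    load_baseline,
    load_scenario,
    make_geometry,
    simulate_companion_channels,
    simulate_decay_cube,
)

__all__ = [
    "RunConfig",
    "StressTestReport",
    "analyze_cube",
    "simulate_scenario_image",
    "run_condition",
    "run_stress_test",
    "inverse_mcr_trend",
    "component_recovery",
]

METRICS = ("MCR", "free_to_bound", "redox")


@dataclass
class RunConfig:
    """Settings of a simulation-analysis run."""

    tile: int = 64  # image side in pixels (native 0.41 um pitch)
    photons_per_pixel: float = 500.0
    binning: int = 3
    n_images: int = 20
    min_photons: float = 100.0
    chi2_range: tuple[float, float] = (0.9, 1.3)
    bin_width_ns: float = 0.05
    hist_range_ns: tuple[float, float] = (0.0, 6.0)
    base_seed: int = 0
    geometry_kwargs: dict = field(default_factory=dict)

    def meta(self) -> AcquisitionMeta:
        return AcquisitionMeta().tile(self.tile)

    def image_seeds(self, n: int, offset: int = 0) -> np.ndarray:
        """Deterministic per-image seeds derived from the base seed."""
        rng = np.random.default_rng((self.base_seed, offset))
        return rng.integers(0, 2**31 - 1, size=n)


def simulate_scenario_image(
    config: RunConfig, scenario: ScenarioConfig, seed: int
):
    """One synthetic acquisition: decay cube + FAD and stain channels."""
    meta = config.meta()
    irf = gaussian_irf(meta)
    geom = make_geometry(meta, seed=int(seed), **config.geometry_kwargs)
    decays = apply_scenario(load_baseline(), scenario)
    cube = simulate_decay_cube(
        geom,
        decays,
        irf,
        meta,
        photons_per_pixel=config.photons_per_pixel,
        seed=int(seed) + 1,
    )
    fad, stain = simulate_companion_channels(geom, scenario, seed=int(seed) + 2)
    return cube, geom, fad, stain


def analyze_cube(
    cube,
    config: RunConfig,
    fad_image: np.ndarray | None = None,
    comps=None,
) -> tuple[MetricsReport, object]:
    """Full single-image analysis; returns the metrics and the ComponentSet.

    With ``comps=None`` the four Gaussian pools are fitted to this image's
    own histogram; passing a reference ComponentSet (e.g. fitted to a
    pooled control histogram) instead assigns intensities against fixed
    pool positions — the lifetime pools are molecular species whose
    positions do not move under pharmacology, only their intensities do.
    """
    fit = fit_image(
        cube,
        k=config.binning,
        min_photons=config.min_photons,
        chi2_range=config.chi2_range,
    )
    hist = lifetime_histogram(
        fit, bin_width_ns=config.bin_width_ns, range_ns=config.hist_range_ns
    )
    if comps is None:
        comps = fit_gaussians(hist, 4)
    intensities = component_intensities(fit, comps)
    ftb = free_to_bound(fit)
    if fad_image is not None:
        nadh = cube.intensity
        _, redox = redox_image(fad_image, nadh, mask=fit.qc_mask)
    else:
        redox = np.nan
    return (
        MetricsReport(
            mcr=mcr(intensities),
            free_to_bound=ftb,
            redox=redox,
            component_intensities=intensities,
            n_qc_pixels=int(fit.qc_mask.sum()),
            extras={"centers": comps.centers, "widths": comps.widths},
        ),
        comps,
    )


def run_condition(
    config: RunConfig,
    scenario: ScenarioConfig | str,
    n_images: int | None = None,
    seed_offset: int = 0,
    comps=None,
) -> pd.DataFrame:
    """Simulate and analyze a batch of images for one condition.

    Returns one row per image (metrics + component intensities + seed);
    aggregate with mean/std.  A failed image is skipped and counted in the
    ``failed`` attribute of the frame.
    """
    if isinstance(scenario, str):
        scenario = load_scenario(scenario)
    n = n_images if n_images is not None else config.n_images
    rows = []
    failed = 0
    for seed in config.image_seeds(n, offset=seed_offset):
        try:
            cube, geom, fad, stain = simulate_scenario_image(config, scenario, seed)
            report, _ = analyze_cube(cube, config, fad_image=fad, comps=comps)
        except Exception:  # noqa: BLE001 - a bad image must not kill the batch
            failed += 1
            continue
        c = report.component_intensities
        rows.append(
            {
                "scenario": scenario.name,
                "seed": int(seed),
                "MCR": report.mcr,
                "free_to_bound": report.free_to_bound,
                "redox": report.redox,
                "C1": c[0],
                "C2": c[1],
                "C3": c[2],
                "C4": c[3],
                "n_qc_pixels": report.n_qc_pixels,
            }
        )
    frame = pd.DataFrame(rows)
    frame.attrs["failed"] = failed
    frame.attrs["oxidative_activity"] = scenario.oxidative_activity
    frame.attrs["expected_direction"] = dict(scenario.expected_direction)
    return frame


@dataclass
class StressTestReport:
    """Per-condition metrics with significance and direction flags."""

    table: pd.DataFrame  # one row per (scenario, metric)
    per_image: pd.DataFrame  # all per-image rows
    alpha: float = 0.05

    @property
    def all_match(self) -> bool:
        declared = self.table[self.table["expected"].notna()]
        return bool((declared["flag"] == "match").all())


FLAT_MARGIN = 0.10  # relative equivalence margin for "flat" expectations


def _direction_flag(
    expected: str,
    delta: float,
    p_value: float,
    alpha: float,
    rel_ci: tuple[float, float] | None = None,
) -> str:
    """Flag an observed effect against its expected direction.

    Directional expectations need a significant effect of the right sign.
    "Flat" is an equivalence claim, tested TOST-style: match when the 90%
    confidence interval of the relative difference lies inside the
    +/-FLAT_MARGIN band, mismatch when it lies entirely outside, otherwise
    inconclusive.  (Mere failure to reject zero would flag any systematic
    sub-margin artifact as a change once the comparison is paired.)
    """
    if expected == "flat":
        if rel_ci is None:
            return "inconclusive"
        lo, hi = rel_ci
        if -FLAT_MARGIN < lo and hi < FLAT_MARGIN:
            return "match"
        if lo > FLAT_MARGIN or hi < -FLAT_MARGIN:
            return "mismatch"
        return "inconclusive"
    if p_value >= alpha:
        return "inconclusive"
    observed_up = delta > 0
    return "match" if observed_up == (expected == "up") else "mismatch"


def run_stress_test(
    config: RunConfig,
    scenarios: list[str] | list[ScenarioConfig],
    n_images: int | None = None,
    alpha: float = 0.05,
    paired: bool = True,
) -> StressTestReport:
    """Compare each scenario's metrics against the control.

    With ``paired=True`` (default) every scenario is simulated on the same
    geometry seed stream as the control and compared with a paired t-test —
    the repeated-measures design of a pharmacological injection series,
    where the same culture is imaged across conditions; pairing removes the
    image-to-image geometry variance from the comparison.  With
    ``paired=False`` each scenario gets its own seed stream and Welch's
    unequal-variance t-test is used.  The observed direction of each
    declared metric is flagged against the scenario's expectation.
    """
    loaded = [
        load_scenario(s) if isinstance(s, str) else s for s in scenarios
    ]
    names = [s.name for s in loaded]
    if "control" not in names:
        raise ValueError("a stress test requires the 'control' scenario")
    # The four lifetime pools are fixed once, from a pooled control
    # histogram; per-condition analysis then measures how much intensity
    # each pool carries.  Re-fitting pool positions on every treated image
    # would let a single unstable 4-Gaussian fit corrupt a batch.
    comps_ref = reference_components(config, n_images=n_images)
    frames = {
        s.name: run_condition(
            config,
            s,
            n_images=n_images,
            seed_offset=0 if paired else i,
            comps=comps_ref,
        )
        for i, s in enumerate(loaded)
    }
    control = frames["control"]
    rows = []
    for s in loaded:
        frame = frames[s.name]
        for metric in METRICS:
            values = frame[metric].dropna()
            ref = control[metric].dropna()
            mean, sd = values.mean(), values.std(ddof=1)
            if s.name == "control" or values.empty or ref.empty:
                p_value, delta, flag = np.nan, 0.0, None
            else:
                if paired and len(values) == len(ref):
                    t_res = stats.ttest_rel(values, ref)
                    se = float(
                        (values.to_numpy() - ref.to_numpy()).std(ddof=1)
                        / np.sqrt(len(values))
                    )
                else:
                    t_res = stats.ttest_ind(values, ref, equal_var=False)
                    se = float(
                        np.sqrt(
                            values.var(ddof=1) / len(values)
                            + ref.var(ddof=1) / len(ref)
                        )
                    )
                p_value = float(t_res.pvalue)
                delta = float(mean - ref.mean())
                scale = abs(ref.mean())
                rel_ci = (
                    (delta - 1.645 * se) / scale,
                    (delta + 1.645 * se) / scale,
                )
                expected = s.expected_direction.get(metric)
                flag = (
                    _direction_flag(expected, delta, p_value, alpha, rel_ci)
                    if expected
                    else None
                )
            rows.append(
                {
                    "scenario": s.name,
                    "metric": metric,
                    "mean": mean,
                    "sd": sd,
                    "n": len(values),
                    "delta_vs_control": delta if s.name != "control" else 0.0,
                    "p_value": p_value,
                    "expected": s.expected_direction.get(metric),
                    "flag": flag,
                    "oxidative_activity": s.oxidative_activity,
                }
            )
    table = pd.DataFrame(rows)
    per_image = pd.concat(frames.values(), ignore_index=True)
    return StressTestReport(table=table, per_image=per_image, alpha=alpha)


def inverse_mcr_trend(report: StressTestReport):
    """Regress the oxidative-activity proxy on 1/MCR across conditions.

    Mirrors the respirometry comparison: conditions that raise oxidative
    activity deplete mitochondrial NADH, so the proxy should rise with
    MCR^-1.  Returns (slope, intercept, pearson_r, p_value).
    """
    mcr_rows = report.table[report.table["metric"] == "MCR"]
    if len(mcr_rows) < 3:
        raise ValueError("need at least 3 conditions for the MCR^-1 trend")
    inv_mcr = 1.0 / mcr_rows["mean"].to_numpy()
    proxy = mcr_rows["oxidative_activity"].to_numpy()
    fit = stats.linregress(inv_mcr, proxy)
    return (
        float(fit.slope),
        float(fit.intercept),
        float(fit.rvalue),
        float(fit.pvalue),
    )


def reference_components(
    config: RunConfig, n_images: int | None = None, scenario: str = "control"
):
    """Fit the four Gaussian pools to a pooled control-batch histogram."""
    sc = load_scenario(scenario)
    n = min(n_images or config.n_images, 8)  # pooling saturates quickly
    pooled = None
    bin_centers = None
    for seed in config.image_seeds(n, offset=0):
        cube, *_ = simulate_scenario_image(config, sc, seed)
        fit = fit_image(
            cube,
            k=config.binning,
            min_photons=config.min_photons,
            chi2_range=config.chi2_range,
        )
        hist = lifetime_histogram(
            fit, bin_width_ns=config.bin_width_ns, range_ns=config.hist_range_ns
        )
        pooled = hist.weights if pooled is None else pooled + hist.weights
        bin_centers = hist.bin_centers
    from .components import LifetimeHistogram

    return fit_gaussians(
        LifetimeHistogram(bin_centers=bin_centers, weights=pooled), 4
    )


def component_recovery(
    config: RunConfig | None = None,
    n_images: int = 20,
    scenario: str = "control",
) -> pd.DataFrame:
    """Recover the four Gaussian peak centers on a batch of default images.

    The central desk-scale check: simulate ``n_images`` default-scenario
    adipocyte images, run the full pipeline at the configured binning, and
    return the per-image fitted peak centers (columns b1..b4, ns).  Their
    means estimate the four NADH lifetime pools.
    """
    config = config or RunConfig()
    sc = load_scenario(scenario)
    rows = []
    for seed in config.image_seeds(n_images, offset=901):
        cube, geom, fad, stain = simulate_scenario_image(config, sc, seed)
        _, comps = analyze_cube(cube, config, fad_image=fad)
        rows.append(
            {
                "seed": int(seed),
                "b1": comps.centers[0],
                "b2": comps.centers[1],
                "b3": comps.centers[2],
                "b4": comps.centers[3],
                "degenerate": comps.degenerate,
            }
        )
    return pd.DataFrame(rows)
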