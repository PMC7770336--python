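"""Reference study configurations and parameter-recovery workflows.

These functions wire the simulator and the analysis pipeline into the
benchmark experiments the package is validated with: movies are generated
with leading-site positions and heart rates drawn from published rat and
human right-atrial distributions, and the full pipeline must recover the
generating cluster parameters, heart rates, and per-heart dominance.

Reported rat right-atrial values used as generator settings: ex vivo
baseline HR 280.90 +/- 43.00 bpm, 100-uM ACh 192.30 +/- 50.15 bpm, 500-nM
ISO 426.00 +/- 57.12 bpm, physiological range 102.47-502.09 bpm; site
clusters 0.80 +/- 0.09 AU (superior) and 0.24 +/- 0.14 AU (inferior).
Human values: clusters 0.90 +/- 0.05 and 0.36 +/- 0.09 AU, HR range
52.50-118.40 bpm with inferior dominance below 66 bpm and superior
dominance above 81 bpm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cluster_stats import build_cluster_summary, classify_dominance
from .pipeline import AnalysisParams, analyze_movie
from .synthetic import render_movie, simulate_cohort
from .types import (
    Landmarks,
    OAPTemplate,
    PacemakerFocus,
    SimulationConfig,
    TissueGeometry,
)

__all__ = [
    "rat_geometry",
    "human_geometry",
    "run_cluster_recovery",
    "run_hr_recovery",
    "run_failing_cohort",
    "demo_run_config",
    "RAT", "HUMAN",
]

BIG_CL_MS = 1e9  # single-shot focus: fires once within any recording


@dataclass(frozen=True)
class SpeciesStudy:
    """Generator settings for one species' intact-preparation study."""

    mu_sup: float
    sigma_sup: float
    mu_inf: float
    sigma_inf: float
    hr_conditions: dict[str, tuple[float, float]]  # condition -> (mean, sd) bpm
    hr_range_bpm: tuple[float, float]
    superior_conditions: tuple[str, ...]  # conditions whose sites are superior
    frame_rate_hz: float
    spatial_kernel_px: int
    min_cl_ms: float
    conduction_velocity_mm_per_ms: float
    template: OAPTemplate
    pixel_pitch_mm: float


RAT = SpeciesStudy(
    mu_sup=0.80,
    sigma_sup=0.09,
    mu_inf=0.24,
    sigma_inf=0.14,
    hr_conditions={"ACh": (192.30, 50.15), "ISO": (426.00, 57.12)},
    hr_range_bpm=(102.47, 502.09),
    superior_conditions=("ISO",),
    frame_rate_hz=1000.0,
    spatial_kernel_px=3,
    min_cl_ms=100.0,
    conduction_velocity_mm_per_ms=0.5,
    template=OAPTemplate(upstroke_ms=5.0, apd_ms=60.0),
    pixel_pitch_mm=0.1,
)

HUMAN = SpeciesStudy(
    mu_sup=0.90,
    sigma_sup=0.05,
    mu_inf=0.36,
    sigma_inf=0.09,
    # low-rate recordings originate inferiorly (< 66 bpm), high-rate
    # recordings superiorly (> 81 bpm)
    hr_conditions={"slow": (59.0, 4.0), "fast": (99.0, 11.0)},
    hr_range_bpm=(52.50, 118.40),
    superior_conditions=("fast",),
    frame_rate_hz=500.0,
    spatial_kernel_px=5,
    min_cl_ms=400.0,
    conduction_velocity_mm_per_ms=0.8,
    template=OAPTemplate(upstroke_ms=8.0, apd_ms=150.0),
    pixel_pitch_mm=0.5,
)

RAT_BASELINE_HR_BPM = 280.90
RAT_FAILING_HR_BPM = {"baseline": 289.47, "ACh": 150.0, "ISO": 372.67}

GRID_PX = 60
IVC_PX = (50, 30)
SVC_PX = (10, 30)


def _geometry(pixel_pitch_mm: float) -> TissueGeometry:
    return TissueGeometry(
        height_px=GRID_PX,
        width_px=GRID_PX,
        pixel_pitch_mm=pixel_pitch_mm,
        landmarks=Landmarks(ivc_px=IVC_PX, svc_px=SVC_PX),
    )


def rat_geometry() -> TissueGeometry:
    """60 x 60 px field at 0.1 mm/px (6 mm rat RA field of view)."""
    return _geometry(RAT.pixel_pitch_mm)


def human_geometry() -> TissueGeometry:
    """60 x 60 px field at 0.5 mm/px (30 mm human RA field of view)."""
    return _geometry(HUMAN.pixel_pitch_mm)


def _site_pixel(geometry: TissueGeometry, y_au: float, x_mm: float) -> tuple[int, int]:
    """Pixel at normalized axis position y with perpendicular offset x."""
    ivc = np.asarray(geometry.landmarks.ivc_px, dtype=float)
    svc = np.asarray(geometry.landmarks.svc_px, dtype=float)
    axis = svc - ivc
    u = axis / np.hypot(*axis)
    n = np.array([-u[1], u[0]])
    pos = ivc + y_au * axis + (x_mm / geometry.pixel_pitch_mm) * n
    r = int(np.clip(np.floor(pos[0] + 0.5), 1, geometry.height_px - 2))
    c = int(np.clip(np.floor(pos[1] + 0.5), 1, geometry.width_px - 2))
    return r, c


def _beat_train_config(
    study: SpeciesStudy,
    geometry: TissueGeometry,
    condition: str,
    cl_ms: float,
    y_sites: np.ndarray,
    x_sites_mm: np.ndarray,
    noise_sd: float,
    seed: int,
) -> SimulationConfig:
    """One recording in which every beat originates at its own drawn site.

    Each beat is produced by a single-shot focus (it fires once); the foci
    are staggered by the recording's cycle length.
    """
    start_ms = 40.0
    foci = [
        PacemakerFocus(
            position_px=_site_pixel(geometry, y, x),
            intrinsic_cl_ms={condition: BIG_CL_MS},
            first_firing_ms=start_ms + k * cl_ms,
        )
        for k, (y, x) in enumerate(zip(y_sites, x_sites_mm))
    ]
    duration = start_ms + (len(foci) - 1) * cl_ms + study.template.support_ms + 80.0
    return SimulationConfig(
        geometry=geometry,
        foci=foci,
        conduction_velocity_mm_per_ms=study.conduction_velocity_mm_per_ms,
        template=study.template,
        noise_sd=noise_sd,
        frame_rate_hz=study.frame_rate_hz,
        duration_ms=duration,
        seed=seed,
        condition=condition,
    )


def _analysis_params(study: SpeciesStudy, condition: str) -> AnalysisParams:
    return AnalysisParams(
        spatial_kernel_px=study.spatial_kernel_px,
        min_cl_ms=study.min_cl_ms,
        condition=condition,
    )


def run_cluster_recovery(
    study: SpeciesStudy,
    seed: int,
    n_beats: int = 320,
    beats_per_movie: int = 10,
    noise_sd: float = 0.05,
) -> dict:
    """Cluster-parameter recovery on a simulated two-cluster dataset.

    Beats are split evenly across the study's conditions; each condition's
    true leading sites are drawn from that cluster's normal distribution
    (superior for the study's superior conditions, inferior otherwise) and
    the per-recording heart rate from the condition's HR distribution,
    truncated to the study's physiological range. The full pipeline
    (filtering, segmentation, AP50 maps, leading sites, projection, exact
    k-means, normal fits, logistic fit) is then run and the fitted cluster
    parameters returned alongside the pooled beats table.
    """
    rng = np.random.default_rng(seed)
    conditions = list(study.hr_conditions)
    per_cond = n_beats // len(conditions)
    lo_hr, hi_hr = study.hr_range_bpm

    frames = []
    for condition in conditions:
        superior = condition in study.superior_conditions
        mu = study.mu_sup if superior else study.mu_inf
        sigma = study.sigma_sup if superior else study.sigma_inf
        hr_mean, hr_sd = study.hr_conditions[condition]
        geometry = _geometry(study.pixel_pitch_mm)

        done = 0
        while done < per_cond:
            n = min(beats_per_movie, per_cond - done)
            if n < 2:
                n = 2  # a recording needs >= 2 beats for a rate
            hr = float(np.clip(rng.normal(hr_mean, hr_sd), lo_hr, hi_hr))
            cl_ms = 60000.0 / hr
            y = rng.normal(mu, sigma, size=n)
            x = rng.normal(0.0, 0.2, size=n)
            cfg = _beat_train_config(
                study,
                geometry,
                condition,
                cl_ms,
                y,
                x,
                noise_sd,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            movie, _truth = render_movie(cfg)
            beats, _ = analyze_movie(
                movie,
                landmarks=geometry.landmarks,
                mask=geometry.mask,
                params=_analysis_params(study, condition),
            )
            beats["true_y"] = y[: len(beats)]
            frames.append(beats)
            done += n

    sites = pd.concat(frames, ignore_index=True)
    summary = build_cluster_summary(
        sites["y_au"].to_numpy(), sites["hr_bpm"].to_numpy()
    )
    return {
        "sites": sites,
        "summary": summary,
        "mu_sup": summary.mu_sup,
        "mu_inf": summary.mu_inf,
        "sigma_sup": summary.sigma_sup,
        "sigma_inf": summary.sigma_inf,
        "n_beats": int(len(sites)),
    }


def run_hr_recovery(
    seed: int,
    hr_bpm: float = RAT_BASELINE_HR_BPM,
    duration_ms: float = 3000.0,
    noise_sd: float = 0.05,
) -> dict:
    """Heart-rate recovery: render a recording at a known cycle length and
    measure the mean pipeline heart rate."""
    geometry = rat_geometry()
    cl_ms = 60000.0 / hr_bpm
    focus = PacemakerFocus(
        position_px=_site_pixel(geometry, RAT.mu_sup, 0.0),
        intrinsic_cl_ms={"baseline": cl_ms},
        first_firing_ms=40.0,
    )
    cfg = SimulationConfig(
        geometry=geometry,
        foci=[focus],
        conduction_velocity_mm_per_ms=RAT.conduction_velocity_mm_per_ms,
        template=RAT.template,
        noise_sd=noise_sd,
        frame_rate_hz=RAT.frame_rate_hz,
        duration_ms=duration_ms,
        seed=seed,
        condition="baseline",
    )
    movie, truth = render_movie(cfg)
    beats, _ = analyze_movie(
        movie,
        landmarks=geometry.landmarks,
        mask=geometry.mask,
        params=_analysis_params(RAT, "baseline"),
    )
    return {
        "beats": beats,
        "mean_hr_bpm": float(beats["hr_bpm"].mean()),
        "true_hr_bpm": hr_bpm,
        "n_beats": int(len(beats)),
    }


def run_failing_cohort(
    seed: int,
    n_superior_hearts: int = 4,
    n_inferior_hearts: int = 2,
    beats_per_condition: int = 6,
    noise_sd: float = 0.05,
    threshold: float = 0.95,
) -> dict:
    """Failing-heart cohort: each heart exposes a single pacemaker region.

    Each heart's sole focus sits in either the superior or the inferior
    cluster region (drawn from the cluster normal truncated to +/-1.5
    sigma, the anatomical extent of the region) and is recorded under
    three conditions. Dominance is classified per heart after pooled
    two-cluster assignment of all beats.
    """
    rng = np.random.default_rng(seed)
    geometry = rat_geometry()
    configs: list[SimulationConfig] = []
    heart_meta: list[tuple[str, str, str]] = []  # heart_id, region, condition

    def truncated(mu: float, sigma: float) -> float:
        while True:
            v = rng.normal(mu, sigma)
            if abs(v - mu) <= 1.5 * sigma:
                return v

    hearts = [("sup", i) for i in range(n_superior_hearts)] + [
        ("inf", i) for i in range(n_inferior_hearts)
    ]
    for region, i in hearts:
        heart_id = f"{region}_{i + 1}"
        if region == "sup":
            y = truncated(RAT.mu_sup, RAT.sigma_sup)
        else:
            y = truncated(RAT.mu_inf, RAT.sigma_inf)
        x = float(rng.normal(0.0, 0.2))
        position = _site_pixel(geometry, y, x)
        for condition, hr in RAT_FAILING_HR_BPM.items():
            cl_ms = 60000.0 / hr
            focus = PacemakerFocus(
                position_px=position,
                intrinsic_cl_ms={condition: cl_ms},
                first_firing_ms=40.0,
            )
            configs.append(
                SimulationConfig(
                    geometry=geometry,
                    foci=[focus],
                    conduction_velocity_mm_per_ms=RAT.conduction_velocity_mm_per_ms,
                    template=RAT.template,
                    noise_sd=noise_sd,
                    frame_rate_hz=RAT.frame_rate_hz,
                    duration_ms=40.0 + beats_per_condition * cl_ms + 150.0,
                    seed=int(rng.integers(0, 2**31 - 1)),
                    condition=condition,
                )
            )
            heart_meta.append((heart_id, region, condition))

    results = simulate_cohort(configs)
    frames = []
    for (heart_id, region, condition), (movie, _truth), cfg in zip(
        heart_meta, results, configs
    ):
        beats, _ = analyze_movie(
            movie,
            landmarks=geometry.landmarks,
            mask=geometry.mask,
            params=_analysis_params(RAT, condition),
        )
        beats.insert(0, "heart_id", heart_id)
        beats["true_region"] = region
        frames.append(beats)
    sites = pd.concat(frames, ignore_index=True)

    summary = build_cluster_summary(
        sites["y_au"].to_numpy(), sites["hr_bpm"].to_numpy()
    )
    sites["cluster"] = summary.assignments
    calls = classify_dominance(sites, threshold=threshold)
    n_isan = sum(1 for c in calls if c.call == "iSAN_only")
    n_ssan = sum(1 for c in calls if c.call == "sSAN_only")
    return {
        "sites": sites,
        "summary": summary,
        "calls": calls,
        "n_iSAN_only": n_isan,
        "n_sSAN_only": n_ssan,
        "n_hearts": len(calls),
    }


def demo_run_config(seed: int = 7) -> dict:
    """A small two-heart run config for the ``pacemap all`` entry point."""
    rng = np.random.default_rng(seed)
    geometry = {
        "height_px": GRID_PX,
        "width_px": GRID_PX,
        "pixel_pitch_mm": RAT.pixel_pitch_mm,
        "landmarks": {"ivc_px": list(IVC_PX), "svc_px": list(SVC_PX)},
    }
    sims = []
    for heart_id, y in (("H1", RAT.mu_sup), ("H2", RAT.mu_inf)):
        for condition, (hr, _sd) in RAT.hr_conditions.items():
            cl = 60000.0 / hr
            sims.append(
                {
                    "heart_id": heart_id,
                    "geometry": geometry,
                    "foci": [
                        {
                            "position_px": list(
                                _site_pixel(rat_geometry(), y, 0.0)
                            ),
                            "intrinsic_cl_ms": {condition: cl},
                            "first_firing_ms": 40.0,
                        }
                    ],
                    "conduction_velocity_mm_per_ms": RAT.conduction_velocity_mm_per_ms,
                    "template": {"upstroke_ms": 5.0, "apd_ms": 60.0},
                    "noise_sd": 0.05,
                    "frame_rate_hz": RAT.frame_rate_hz,
                    "duration_ms": 40.0 + 5 * cl + 150.0,
                    "seed": int(rng.integers(0, 2**31 - 1)),
                    "condition": condition,
                }
            )
    return {"seed": seed, "simulations": sims, "analysis": {}, "cluster": {}}
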