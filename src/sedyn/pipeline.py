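"""End-to-end pipeline driver: config → correlators → fits → SED tables.

The pipeline reads (or generates) a rigid-molecule trajectory and optional
stress series, computes the configured correlators, extracts transport
coefficients and relaxation times, and writes per-stage CSV tables plus a
JSON run manifest (seed, package version, all resolved parameters).  Output
is bit-reproducible for a fixed seed and config.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .correlations import (
    CorrelationResult,
    angular_msd,
    angular_track,
    angular_velocity_acf,
    default_lag_grid,
    intermediate_scattering,
    legendre_autocorrelation,
    msd,
)
from .generators import GeneratorSpec, gen_combined_rigid_water
from .hbonds import HBCriterion, hbond_correlation, hbond_indicator_series, tau_hb
from .heterogeneity import chi4_rotational, chi4_translational, joint_van_hove, peak_time
from .sed import sed_ratio_table
from .transport import (
    TransportRecord,
    fit_diffusion,
    green_kubo_viscosity,
    kww_fit,
    rotational_diffusion_gk,
    tau_alpha,
)
from .trajectory import read_extended_xyz, read_scalar_series, unwrap_periodic

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run.

    Either ``trajectory_path`` (extended XYZ) or ``generator`` must be set.
    """

    output_dir: str = "sedyn_out"
    temperature: float | None = None  # K, required
    trajectory_path: str | None = None
    stress_path: str | None = None
    generator: GeneratorSpec | None = None
    k: float = 3.0  # Å⁻¹, F_s / χ_t wave number
    legendre_orders: tuple[int, ...] = (1, 2, 3, 6)
    omega_stride: int = 1  # frames between orientation samples for ω
    origin_stride: int = 10
    hbond_criterion: HBCriterion = field(default_factory=HBCriterion)
    run_hbond: bool = False
    run_chi4: bool = True
    run_vanhove: bool = False
    vanhove_times: tuple[float, ...] = ()
    seed: int = 0

    def validate(self) -> None:
        if self.temperature is None or not self.temperature > 0:
            raise ValueError("config requires a positive temperature (K)")
        if self.trajectory_path is None and self.generator is None:
            raise ValueError("config needs a trajectory_path or a generator spec")
        if not self.k > 0:
            raise ValueError("wave number k must be positive")
        if not set(self.legendre_orders) <= set(range(1, 7)):
            raise ValueError("Legendre orders must be within 1..6")

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        gen = raw.pop("generator", None)
        hb = raw.pop("hbond_criterion", None)
        cfg = cls(**raw)
        if gen is not None:
            gen.pop("site_geometry", None)
            cfg.generator = GeneratorSpec(**gen)
        if hb is not None:
            cfg.hbond_criterion = HBCriterion(**hb)
        for tup in ("legendre_orders", "vanhove_times"):
            setattr(cfg, tup, tuple(getattr(cfg, tup)))
        return cfg


def _corr_to_frame(res: CorrelationResult) -> pd.DataFrame:
    return pd.DataFrame({
        "lag": res.lags, "value": res.values,
        "stderr": res.stderr, "n_origins": res.n_origins,
    })


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every configured stage; returns a summary dict and writes files.

    On a stage failure, raises :class:`PipelineError` naming the stage and
    marks the manifest as partial.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "partial": True,
        "config": _config_dict(config),
        "stages": [],
    }

    def save_manifest():
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True, default=str)

    def stage(name):
        manifest["stages"].append(name)
        save_manifest()

    try:
        # --- input stage -------------------------------------------------
        stage("input")
        sites = None
        if config.generator is not None:
            spec = dataclasses.replace(config.generator, seed=config.seed)
            traj, sites = gen_combined_rigid_water(spec)
        else:
            traj = read_extended_xyz(config.trajectory_path)
        series = read_scalar_series(config.stress_path) if config.stress_path else None
        utraj = unwrap_periodic(traj)
        if "unwrapped_centers" in traj.metadata:
            utraj = dataclasses.replace(
                utraj, centers=traj.metadata["unwrapped_centers"], wrapped=False
            )

        record = TransportRecord(T=config.temperature,
                                 volume=traj.box_edge**3, provenance={})
        lag_grid = default_lag_grid(traj.n_frames, traj.frame_interval)

        # --- correlate ---------------------------------------------------
        stage("correlate")
        results: dict[str, CorrelationResult] = {}
        results["msd"] = msd(utraj, lag_grid, origin_stride=config.origin_stride)
        track = angular_track(traj, stride=config.omega_stride)
        amsd_grid = default_lag_grid(track.phi.shape[0], track.stride)
        results["angular_msd"] = angular_msd(track, amsd_grid,
                                             origin_stride=config.origin_stride)
        n_acf = min(track.Omega.shape[0], 200)
        results["c_omega"] = angular_velocity_acf(
            track, np.arange(n_acf) * track.stride, origin_stride=1)
        for ell in config.legendre_orders:
            results[f"c_{ell}"] = legendre_autocorrelation(
                traj, ell, lag_grid, origin_stride=config.origin_stride)
        results["f_s"] = intermediate_scattering(
            utraj, config.k, lag_grid, origin_stride=config.origin_stride)
        for name, res in results.items():
            _corr_to_frame(res).to_csv(out / f"corr_{name}.csv", index=False)

        # --- fit ---------------------------------------------------------
        stage("fit")
        fits: dict[str, dict] = {}
        D_t, D_t_se = fit_diffusion(results["msd"], divisor=6.0)
        record.D_t = D_t
        record.provenance["D_t"] = {"route": "msd_slope/6", "stderr": D_t_se}
        D_r, D_r_se = fit_diffusion(results["angular_msd"], divisor=4.0)
        record.D_r_msd = D_r
        record.provenance["D_r_msd"] = {"route": "angular_msd_slope/4", "stderr": D_r_se}
        try:
            D_r_gk, D_r_gk_se = rotational_diffusion_gk(results["c_omega"])
            record.D_r_gk = D_r_gk
            record.provenance["D_r_gk"] = {"route": "int C_Omega dt", "stderr": D_r_gk_se}
        except (ValueError, RuntimeError) as err:
            record.provenance["D_r_gk"] = {"error": str(err)}
        for ell in config.legendre_orders:
            fit = kww_fit(results[f"c_{ell}"])
            record.tau_ell[ell] = fit.tau
            fits[f"c_{ell}"] = {"A": fit.A, "tau": fit.tau, "beta": fit.beta,
                                "integrated_time": fit.integrated_time}
        record.tau_alpha = tau_alpha(results["f_s"])
        pd.DataFrame(fits).T.to_csv(out / "kww_fits.csv")

        # --- viscosity ---------------------------------------------------
        if series is not None:
            stage("viscosity")
            from .correlations import series_acf

            acf = series_acf(series)
            _corr_to_frame(acf).to_csv(out / "corr_stress_acf.csv", index=False)
            eta, eta_se, diag = green_kubo_viscosity(
                acf, volume=traj.box_edge**3, T=config.temperature)
            record.eta = eta
            record.provenance["eta"] = {"stderr": eta_se, **diag}

        # --- hbond -------------------------------------------------------
        if config.run_hbond and sites is not None:
            stage("hbond")
            hb = hbond_indicator_series(sites, config.hbond_criterion)
            c = hbond_correlation(hb)
            _corr_to_frame(c).to_csv(out / "corr_hbond.csv", index=False)
            record.tau_hb = tau_hb(c)

        # --- chi4 --------------------------------------------------------
        if config.run_chi4:
            stage("chi4")
            # cap chi4 lags at half the trajectory so every lag keeps >= 2
            # configuration samples
            chi_grid = default_lag_grid(traj.n_frames // 2, traj.frame_interval)
            chi_t = chi4_translational(utraj, config.k, chi_grid,
                                       origin_stride=config.origin_stride)
            chi_r = chi4_rotational(traj, config.legendre_orders[0], chi_grid,
                                    origin_stride=config.origin_stride)
            for nm, chi in (("chi_t", chi_t), ("chi_r", chi_r)):
                pd.DataFrame({"lag": chi.lags, "chi": chi.chi,
                              "stderr": chi.stderr}).to_csv(out / f"{nm}.csv", index=False)
                try:
                    record.__setattr__("tau_t" if nm == "chi_t" else "tau_r",
                                       peak_time(chi))
                except ValueError as err:
                    record.provenance[nm] = {"peak_error": str(err)}

        # --- vanhove -----------------------------------------------------
        if config.run_vanhove and config.vanhove_times:
            stage("vanhove")
            jvh = joint_van_hove(utraj, config.vanhove_times)
            for i, t in enumerate(jvh.times):
                pd.DataFrame(jvh.surface[i], index=jvh.r_centers,
                             columns=jvh.theta_centers).to_csv(
                    out / f"vanhove_t{t:g}.csv")

        # --- sed ---------------------------------------------------------
        stage("sed")
        report = sed_ratio_table([record], reference_T=config.temperature,
                                 orders=tuple(config.legendre_orders))
        report.table.to_csv(out / "sed_table.csv", index=False)
        rec_dict = dataclasses.asdict(record)
        with open(out / "transport_record.json", "w") as fh:
            json.dump(rec_dict, fh, indent=1, sort_keys=True, default=str)

        manifest["partial"] = False
        save_manifest()
        return {"record": record, "results": results, "sed": report,
                "output_dir": str(out)}
    except Exception as err:
        current = manifest["stages"][-1] if manifest["stages"] else "input"
        save_manifest()
        raise PipelineError(f"stage '{current}' failed: {err}") from err


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    if config.generator is not None:
        d["generator"] = config.generator.as_metadata()
    return d
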