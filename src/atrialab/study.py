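"""Study orchestration: the 12 region x genotype presets, runs and summaries.

One entry point per experiment of the study (fit, cell biomarkers,
restitution, tissue cross-field, VW scan, phase analysis), each writing a
result bundle (manifest + delimited tables) to an output directory so that
summaries are traceable to files.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from .cell import ModelSpec
from .params import MUTATIONS, REGIONS, get_mutation, get_region
from .protocols import (PacingProtocol, biomarker_delta, max_slope,
                        pace_train, restitution)

__all__ = ["StudyConfig", "PRESETS", "run_study", "export_summary",
           "delta_table"]

GENOTYPES = ("WT", "KCNH2-T436M", "KCNH2-T895M", "KCNE3-V17M")
#: the 12 study models
PRESETS = tuple(f"{m}/{r}" for m, r in product(GENOTYPES, ("RA", "LA", "PV")))

EXPERIMENTS = ("fit", "cell", "restitution", "tissue", "scan-vw", "phase")


@dataclass
class StudyConfig:
    experiment: str
    preset: str = "WT/RA"                 # "<genotype>/<region>"
    outdir: str = "results"
    seed: int = 0
    settings: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.experiment not in EXPERIMENTS:
            raise ValueError(
                f"unknown experiment {self.experiment!r}; one of {EXPERIMENTS}")
        self.spec = parse_preset(self.preset)


def parse_preset(preset: str) -> ModelSpec:
    try:
        genotype, region = preset.split("/")
    except ValueError:
        raise ValueError(f"preset must be '<genotype>/<region>', got {preset!r}")
    get_mutation(genotype)   # raises on unknown names before any computation
    get_region(region)
    return ModelSpec(mutation=genotype, region=region.upper())


def _write_manifest(outdir: Path, config: StudyConfig, runtime: float,
                    outputs: list[str]) -> None:
    manifest = {
        "experiment": config.experiment,
        "preset": config.preset,
        "seed": config.seed,
        "settings": config.settings,
        "version": _version,
        "runtime_s": round(runtime, 3),
        "outputs": outputs,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def run_study(config: StudyConfig):
    """Execute one experiment and write its result bundle to disk."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    outputs: list[str] = []
    s = config.settings

    if config.experiment == "cell":
        proto = PacingProtocol(bcl=s.get("bcl", 1000.0),
                               n_beats=s.get("n_beats", 61))
        run = pace_train(config.spec, proto)
        trace = pd.DataFrame({"t_ms": run.result.t_beat,
                              "v_mV": run.result.analysis_v,
                              "ikr_pA": run.result.current("IKr"),
                              "ito_pA": run.result.current("Ito")})
        trace.to_csv(outdir / "beat61.csv", index=False)
        summary = {"preset": config.preset, "apd90_ms": run.apd90,
                   "peak_ikr_pA": run.peak_ikr, "peak_ito_pA": run.peak_ito,
                   "captured": run.captured,
                   "steady_error_ms": run.steady_error}
        (outdir / "biomarkers.json").write_text(json.dumps(summary, indent=2))
        outputs += ["beat61.csv", "biomarkers.json"]
        result = run

    elif config.experiment == "restitution":
        curve = restitution(config.spec,
                            bcl_min=s.get("bcl_min", 300.0),
                            bcl_max=s.get("bcl_max", 1700.0),
                            step=s.get("step", 10.0))
        curve.to_frame().to_csv(outdir / "restitution.csv", index=False)
        summary = {"preset": config.preset,
                   "max_slope": max_slope(curve),
                   "alternans_bcls": curve.bcl[curve.alternans].tolist()}
        (outdir / "restitution.json").write_text(json.dumps(summary, indent=2))
        outputs += ["restitution.csv", "restitution.json"]
        result = curve

    elif config.experiment == "fit":
        from .clamp import ClampDataset
        from .ga import GAConfig, evolve
        datasets = [ClampDataset.from_csv(p) for p in s["datasets"]]
        cfg = GAConfig(population=s.get("population", 1000),
                       generations=s.get("generations", 20),
                       seed=config.seed)
        fit = evolve(cfg, s["free_names"], datasets)
        from .params import save_parameter_set
        save_parameter_set(fit.best, outdir / "fitted_params.yaml")
        fit.to_frame().to_csv(outdir / "convergence.csv", index=False)
        outputs += ["fitted_params.yaml", "convergence.csv"]
        result = fit

    elif config.experiment in ("tissue", "scan-vw", "phase"):
        from .tissue import (CrossFieldProtocol, TissueGrid, run_cross_field,
                             scan_vw, steady_state_1hz)
        grid_kw = dict(size=tuple(s.get("size", (2.5, 2.5))),
                       dx=s.get("dx", 0.03),
                       model=s.get("model", "courtemanche"))
        if grid_kw["model"] == "courtemanche":
            grid_kw["spec"] = config.spec
        proto = CrossFieldProtocol(**s.get("protocol", {}))
        init = None
        if grid_kw["model"] == "courtemanche" and s.get("preload", True):
            init = steady_state_1hz(config.spec)
        if config.experiment == "scan-vw":
            coarse = np.asarray(s.get("coarse",
                                      np.arange(150.0, 320.0, 10.0)))
            vw = scan_vw(lambda: TissueGrid(**grid_kw), proto, coarse,
                         initial=init)
            rows = [{"interval_ms": iv, "label": lab, "lifespan_ms": ls,
                     "sustained": sus}
                    for iv, (lab, ls, sus) in vw.lifespans.items()]
            pd.DataFrame(rows).to_csv(outdir / "vw_scan.csv", index=False)
            summary = {"preset": config.preset, "lower": vw.lower,
                       "upper": vw.upper, "width_ms": vw.width,
                       "class_fractions": vw.class_fractions()}
            (outdir / "vw.json").write_text(json.dumps(summary, indent=2))
            outputs += ["vw_scan.csv", "vw.json"]
            result = vw
        else:
            grid = TissueGrid(**grid_kw)
            out = run_cross_field(grid, proto, initial=init)
            np.save(outdir / "snapshots.npy", out.snapshots.v)
            meta = {"preset": config.preset, "interval_ms": out.interval,
                    "label": out.label, "lifespan_ms": out.lifespan,
                    "cycles": out.cycles, "dx_cm": out.snapshots.dx,
                    "t0_ms": float(out.snapshots.t[0]),
                    "dt_ms": float(np.diff(out.snapshots.t[:2])[0])}
            (outdir / "outcome.json").write_text(json.dumps(meta, indent=2))
            outputs += ["snapshots.npy", "outcome.json"]
            result = out
            if config.experiment == "phase":
                from .phase import enclosing_ellipse, phase_map, track_tip
                movie = phase_map(out.snapshots.t, out.snapshots.v.astype(float),
                                  dx=out.snapshots.dx)
                tracks = track_tip(movie)
                rows = []
                for k, tr in enumerate(tracks):
                    ell = enclosing_ellipse(tr)
                    rows.append({"track": k, "chirality": tr.chirality,
                                 "t_start_ms": tr.t[0], "t_end_ms": tr.t[-1],
                                 "ellipse_area_cm2": ell.area})
                pd.DataFrame(rows).to_csv(outdir / "tips.csv", index=False)
                outputs += ["tips.csv"]
                result = (out, tracks)
    _write_manifest(outdir, config, time.time() - t0, outputs)
    return result


def delta_table(region: str, protocol: PacingProtocol = PacingProtocol(),
                mutations: tuple = ("KCNH2-T436M", "KCNH2-T895M", "KCNE3-V17M")
                ) -> pd.DataFrame:
    """Mutant-vs-WT percent changes of the single-cell biomarkers."""
    wt = pace_train(ModelSpec("WT", region), protocol)
    frames = []
    for mut in mutations:
        run = pace_train(ModelSpec(mut, region), protocol)
        frames.append(biomarker_delta(run, wt))
    return pd.concat(frames, ignore_index=True)


def export_summary(bundles: list[str | Path], out_path: str | Path | None = None
                   ) -> pd.DataFrame:
    """Assemble region x genotype matrices from result bundles on disk.

    Missing cells are rendered as NaN (an explicit missing marker), never
    as zero.  Returns a long-format frame (and optionally writes CSV).
    """
    rows = []
    for b in bundles:
        b = Path(b)
        man = json.loads((b / "manifest.json").read_text())
        preset = man["preset"]
        genotype, region = preset.split("/")
        for name in man["outputs"]:
            if not name.endswith(".json"):
                continue
            data = json.loads((b / name).read_text())
            for key, val in data.items():
                if isinstance(val, (int, float)) and key != "seed":
                    rows.append({"genotype": genotype, "region": region,
                                 "experiment": man["experiment"],
                                 "metric": key, "value": val,
                                 "source": str(b / name)})
    df = pd.DataFrame(rows)
    if out_path is not None:
        df.to_csv(out_path, index=False)
    return df
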