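"""Volume/plan I/O, pipeline configuration, and the end-to-end pipeline.

Volumes travel as NIfTI (.nii/.nii.gz, via nibabel) or NRRD (via
SimpleITK); plans, trajectories and reports as JSON in a documented
schema.  One coordinate convention holds everywhere: 0-based voxel
indices, world mm = origin + index * spacing, axis order (x, y, z) with z
the slice axis.

Plan JSON schema (version 1)::

    {
      "schema_version": 1,
      "prescription_dose_gy": 6.0,
      "source": { air_kerma_strength_u, dose_rate_constant_cgy_h_u,
                  radial_dose_table [[r_mm, g], ...],
                  anisotropy_table [[r_mm, phi], ...], reference_r0_mm, name },
      "needles": [ { needle_id, positions_mm [[x,y,z], ...], times_s [...],
                     step_mm, offset_mm }, ... ],
      "trajectories": [ { points_mm, poly_x, poly_y, tip_mm, length_mm,
                          merged_flag }, ... ]   # optional, index-aligned
    }

The pipeline runs generate -> train -> predict -> digitize -> evaluate ->
dose -> compare on synthetic phantoms and writes every report plus a run
manifest (seeds, versions, timings, output checksums).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import SimpleITK as sitk
import yaml

from . import digitize as dg
from . import dose as ds
from . import evalgeo as ev
from .grid import Volume
from .nn import NetConfig, SegmentationModel, build_model
from .phantom import PhantomConfig, make_phantom
from .train import TrainConfig, predict_mask, train_model

logger = logging.getLogger("hdrneedle")

PLAN_SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# volumes
# ---------------------------------------------------------------------------

def write_volume(volume: Volume, path: str | Path) -> None:
    """Write a Volume as NIfTI (.nii/.nii.gz) or NRRD (.nrrd)."""
    path = Path(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        affine = np.diag(list(volume.spacing) + [1.0])
        affine[:3, 3] = volume.origin
        nib.save(nib.Nifti1Image(np.asarray(volume.data), affine), str(path))
    elif name.endswith(".nrrd"):
        img = sitk.GetImageFromArray(np.ascontiguousarray(np.asarray(volume.data).T))
        img.SetSpacing(tuple(volume.spacing))
        img.SetOrigin(tuple(volume.origin))
        sitk.WriteImage(img, str(path))
    else:
        raise ValueError(f"unknown volume extension: {path.name}")


def read_volume(path: str | Path) -> Volume:
    """Read a NIfTI or NRRD volume; corrupt files raise IOError."""
    path = Path(path)
    name = path.name.lower()
    if not path.exists():
        raise IOError(f"no such file: {path}")
    try:
        if name.endswith((".nii", ".nii.gz")):
            img = nib.load(str(path))
            data = np.asarray(img.dataobj)
            affine = img.affine
            spacing = tuple(float(np.linalg.norm(affine[:3, i])) for i in range(3))
            origin = tuple(float(v) for v in affine[:3, 3])
        elif name.endswith(".nrrd"):
            img = sitk.ReadImage(str(path))
            data = sitk.GetArrayFromImage(img).T
            spacing = tuple(img.GetSpacing())
            origin = tuple(img.GetOrigin())
        else:
            raise ValueError(f"unknown volume extension: {path.name}")
    except ValueError:
        raise
    except Exception as e:  # nibabel/SimpleITK raise various types on corruption
        raise IOError(f"failed to read volume {path}: {e}") from e
    return Volume(np.ascontiguousarray(data), spacing, origin)


# ---------------------------------------------------------------------------
# plans
# ---------------------------------------------------------------------------

def write_plan(plan: ds.Plan, path: str | Path,
               trajectories: list[dg.Trajectory] | None = None) -> None:
    """Serialize a plan (and optionally its trajectories) to schema-1 JSON."""
    doc = {
        "schema_version": PLAN_SCHEMA_VERSION,
        "prescription_dose_gy": plan.prescription_dose_gy,
        "source": plan.source.to_dict(),
        "needles": [n.to_dict() for n in plan.needles],
    }
    if trajectories is not None:
        doc["trajectories"] = [t.to_dict() for t in trajectories]
    Path(path).write_text(json.dumps(doc, indent=2))


def read_plan(path: str | Path) -> tuple[ds.Plan, list[dg.Trajectory] | None]:
    """Read and validate a schema-1 plan JSON.

    Returns ``(plan, trajectories-or-None)``.  Schema violations raise a
    ValueError naming the offending fields.
    """
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise IOError(f"plan file {path} is not valid JSON: {e}") from e
    version = doc.get("schema_version")
    if version != PLAN_SCHEMA_VERSION:
        raise ValueError(f"unsupported plan schema_version: {version!r}")
    logger.debug("read plan %s (schema %s)", path, version)
    missing = [k for k in ("source", "needles") if k not in doc]
    if missing:
        raise ValueError(f"plan is missing fields: {missing}")
    try:
        source = ds.SourceModel.from_dict(doc["source"])
    except KeyError as e:
        raise ValueError(f"plan source block is missing field {e}") from e
    needles = [dg.DwellSet.from_dict(n) for n in doc["needles"]]
    plan = ds.Plan(needles=needles, source=source,
                   prescription_dose_gy=doc.get("prescription_dose_gy", 6.0))
    traj = None
    if "trajectories" in doc:
        traj = [dg.Trajectory.from_dict(t) for t in doc["trajectories"]]
    return plan, traj


# ---------------------------------------------------------------------------
# pipeline configuration
# ---------------------------------------------------------------------------

@dataclass
class DigitizeConfig:
    degree: int = 3
    step_mm: float = 2.5
    offset_mm: float = 0.0
    n_dwells: int = 5
    dwell_time_s: float = 10.0
    min_voxels: int = 5


@dataclass
class DoseConfig:
    source: str = "generic_ir192"  # or "unity"
    bin_width_gy: float = 0.01
    air_kerma_strength_u: float = 40800.0


@dataclass
class PipelineConfig:
    """Everything one end-to-end synthetic run needs, in validated blocks."""

    out_dir: str = "pipeline_out"
    n_train: int = 10
    n_val: int = 3
    compare_attention: bool = False
    seed: int = 0
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    net: NetConfig = field(default_factory=lambda: NetConfig(depth=3, base_channels=8,
                                                             use_attention=True))
    train: TrainConfig = field(default_factory=TrainConfig)
    digitize: DigitizeConfig = field(default_factory=DigitizeConfig)
    dose: DoseConfig = field(default_factory=DoseConfig)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        blocks = {
            "phantom": PhantomConfig,
            "net": NetConfig,
            "train": TrainConfig,
            "digitize": DigitizeConfig,
            "dose": DoseConfig,
        }
        kwargs = {}
        for key, klass in blocks.items():
            if key in d:
                block = d.pop(key)
                if isinstance(block, dict):
                    for fname in ("grid_shape", "spacing_mm", "crop_size",
                                  "scale_range", "tip_depth_fraction"):
                        if fname in block and isinstance(block[fname], list):
                            block[fname] = tuple(block[fname])
                    if key == "train" and isinstance(block.get("loss"), dict):
                        from .nn import LossConfig

                        block["loss"] = LossConfig(**block["loss"])
                    block = klass(**block)
                kwargs[key] = block
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
        return cls(**d, **kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


# ---------------------------------------------------------------------------
# the pipeline
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _build_plan(trajs: list[dg.Trajectory], cfg: PipelineConfig,
                source: ds.SourceModel) -> ds.Plan:
    needles = []
    for i, t in enumerate(trajs):
        n = cfg.digitize.n_dwells
        # shorten the dwell train on needles that cannot hold it
        max_n = int(t.length_mm // cfg.digitize.step_mm) + 1
        needles.append(dg.sample_dwells(
            t, cfg.digitize.step_mm, cfg.digitize.offset_mm,
            min(n, max_n), cfg.digitize.dwell_time_s, needle_id=i,
        ))
    return ds.Plan(needles=needles, source=source)


def _make_source(cfg: DoseConfig) -> ds.SourceModel:
    if cfg.source == "unity":
        return ds.SourceModel.unity()
    if cfg.source == "generic_ir192":
        return ds.SourceModel.generic_ir192(cfg.air_kerma_strength_u)
    raise ValueError(f"unknown source model {cfg.source!r}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run generate -> train -> predict -> digitize -> evaluate -> dose.

    Trains the configured network (and, with ``compare_attention``, its
    gate-free counterpart) on seeded synthetic phantoms, evaluates held-out
    phantoms geometrically and dosimetrically against the analytic ground
    truth, and writes all reports plus a manifest into ``out_dir``.
    Returns the summary dictionary.  Any stage failure raises with the
    stage name; outputs written so far remain on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "pipeline.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    logger.addHandler(fh)
    logger.setLevel(logging.INFO)
    manifest: dict = {
        "seed": config.seed,
        "versions": _versions(),
        "stages": {},
        "outputs": {},
    }
    stage = "generate"
    t_start = time.time()
    try:
        rng = np.random.default_rng(config.seed)
        logger.info("stage %s", stage)
        t0 = time.time()
        cases = []
        for i in range(config.n_train + config.n_val):
            pcfg = dataclasses.replace(config.phantom, seed=int(rng.integers(2 ** 31)))
            vol, truth = make_phantom(pcfg)
            cases.append((vol, truth))
        train_cases = [(v, t.binary_mask) for v, t in cases[:config.n_train]]
        val_cases = cases[config.n_train:]
        val_pairs = [(v, t.binary_mask) for v, t in val_cases]
        manifest["stages"][stage] = {"seconds": time.time() - t0,
                                     "n_train": config.n_train, "n_val": config.n_val}

        variants = [("cnn_ag" if config.net.use_attention else "cnn", config.net)]
        if config.compare_attention:
            other = dataclasses.replace(config.net,
                                        use_attention=not config.net.use_attention)
            variants.append(("cnn_ag" if other.use_attention else "cnn", other))
            variants.sort(key=lambda kv: kv[0])  # stable: cnn first, then cnn_ag

        source = _make_source(config.dose)
        summary: dict = {"cases": {}, "models": {}}
        for name, netcfg in variants:
            stage = f"train[{name}]"
            logger.info("stage %s", stage)
            t0 = time.time()
            model = build_model(netcfg, seed=config.seed)
            tcfg = dataclasses.replace(config.train, seed=config.seed)
            model, history = train_model(model, train_cases, val_pairs, tcfg,
                                         log_fn=logger.info)
            model.save(out / f"weights_{name}.npz")
            history.to_dataframe().to_csv(out / f"history_{name}.csv", index=False)
            manifest["stages"][stage] = {"seconds": time.time() - t0,
                                         "final_val_dice": history.val_dice[-1]}
            summary["models"][name] = {"final_val_dice": history.val_dice[-1],
                                       "final_train_loss": history.train_loss[-1]}

            stage = f"evaluate[{name}]"
            logger.info("stage %s", stage)
            t0 = time.time()
            geo_rows, dvh_rows = [], []
            for ci, (vol, truth) in enumerate(val_cases):
                pred = predict_mask(model, vol, threshold=config.train.threshold)
                pred_traj = dg.digitize_mask(pred, degree=config.digitize.degree,
                                             min_voxels=config.digitize.min_voxels)
                truth_traj = truth.centerlines
                report = ev.evaluate_case(pred, truth.binary_mask, pred_traj, truth_traj)
                geo_rows.append(report.to_dict())

                # dose comparison: same dwell times, manual (= ground truth
                # digitization) vs automatic digitization
                manual_traj = dg.digitize_mask(truth.binary_mask,
                                               degree=config.digitize.degree,
                                               min_voxels=config.digitize.min_voxels)
                manual_plan = _build_plan(manual_traj, config, source)
                dvh_row: dict = {"case": ci}
                usable = [t for t in pred_traj if not t.merged_flag]
                if usable:
                    auto_plan = _build_plan(usable, config, source)
                    manual_dose = ds.dose_grid(vol, manual_plan)
                    auto_dose = ds.dose_grid(vol, auto_plan)
                    # normalize dwell times so the manual plan delivers the
                    # prescription to HR-CTV D90; the identical times (hence
                    # the identical scale, dose being linear in time) apply
                    # to the automatic plan
                    d90_manual = ds.compute_dvh(manual_dose, truth.structures["hrctv"],
                                                config.dose.bin_width_gy).d90
                    if d90_manual > 0:
                        scale = manual_plan.prescription_dose_gy / d90_manual
                        manual_dose.data = manual_dose.data * scale
                        auto_dose.data = auto_dose.data * scale
                    for sname, smask in truth.structures.items():
                        dvh_m = ds.compute_dvh(manual_dose, smask, config.dose.bin_width_gy)
                        dvh_a = ds.compute_dvh(auto_dose, smask, config.dose.bin_width_gy)
                        metric = "d90" if sname == "hrctv" else "d2cc"
                        mv = getattr(dvh_m, metric)
                        av = getattr(dvh_a, metric)
                        entry = {
                            "manual_d90_gy": dvh_m.d90, "auto_d90_gy": dvh_a.d90,
                            "manual_d100_gy": dvh_m.d100, "auto_d100_gy": dvh_a.d100,
                            "manual_d2cc_gy": dvh_m.d2cc, "auto_d2cc_gy": dvh_a.d2cc,
                            "volume_cc": dvh_m.structure_volume_cc,
                        }
                        if mv is not None and av is not None and mv != 0:
                            diff, rel = ds.dose_difference(mv, av)
                            entry[f"{metric}_diff_gy"] = diff
                            entry[f"{metric}_rel_diff"] = rel
                        dvh_row[sname] = entry
                dvh_rows.append(dvh_row)
            summary["cases"][name] = {"geometry": geo_rows, "dvh": dvh_rows}
            (out / f"geo_report_{name}.json").write_text(json.dumps(geo_rows, indent=2))
            (out / f"dvh_report_{name}.json").write_text(json.dumps(dvh_rows, indent=2))
            manifest["stages"][stage] = {"seconds": time.time() - t0}
    except Exception as e:
        logger.error("pipeline failed in stage %s: %s", stage, e)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e
    finally:
        logger.removeHandler(fh)
        fh.close()

    summary_path = out / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2))
    for p in sorted(out.iterdir()):
        if p.is_file() and p.name != "manifest.json":
            manifest["outputs"][p.name] = _sha256(p)
    manifest["total_seconds"] = time.time() - t_start
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return summary


def read_dicom_rt_plan(path: str | Path) -> ds.Plan:  # pragma: no cover - stub
    """DICOM-RT brachytherapy plan import (interface stub).

    The interchange format of this package is the JSON plan schema;
    vendor DICOM-RT dialects vary enough that a robust importer is out of
    scope.  The stub fixes the signature behind which one would live.
    """
    raise NotImplementedError(
        "DICOM-RT plan import is not implemented; convert to the JSON plan "
        "schema (see read_plan/write_plan)"
    )


def _versions() -> dict:
    import nibabel
    import numba
    import scipy

    from . import __version__

    return {
        "hdrneedle": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "numba": numba.__version__,
        "nibabel": nibabel.__version__,
        "SimpleITK": sitk.__version__ if hasattr(sitk, "__version__") else "unknown",
    }
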