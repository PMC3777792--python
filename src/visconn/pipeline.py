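"""End-to-end pipeline: phantom cohort -> tensors -> tractography -> VISC ->
voxel-based statistics -> LDV regressions.

The pipeline mirrors the study design: a group of control realisations and
one or more lesioned subjects, all on a common grid, each tracked with the
same deterministic parameters.  Per subject and metric (VISC, FA, MD) a
one-tailed voxel-wise t-test against the controls yields a significance
mask; the log of its voxel count (LDV) is regressed against the subjects'
sensorimotor scores.  Everything is reproducible from the master seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .connectivity import ViscParams, VoxelGrid, build_direct, compute_visc
from .dti import TensorField, compute_fa, compute_md, fit_tensor
from .phantom import (
    BundleSpec,
    LesionSpec,
    PhantomSpec,
    generate_phantom,
    synthesize_dwi,
    uniform_gradient_directions,
)
from .stats import difference_volume, ldv, simple_regression, voxelwise_ttest
from .tractography import TrackingParams, filter_fibers, generate_seeds, track_all

logger = logging.getLogger("visconn")

__all__ = ["SubjectSpec", "PipelineConfig", "run_pipeline", "metric_maps_for_field"]

#: default one-tailed test direction per metric: lesions reduce anisotropy
#: and connectivity but elevate diffusivity
DEFAULT_TAILS = {
    "VISC": "controls_greater",
    "FA": "controls_greater",
    "MD": "subject_greater",
}


@dataclass
class SubjectSpec:
    """One lesioned subject: lesion geometry plus a sensorimotor score."""

    lesion: LesionSpec
    fm_score: float
    name: str = ""


@dataclass
class PipelineConfig:
    """Serializable description of a full phantom-cohort run."""

    phantom: PhantomSpec
    subjects: list[SubjectSpec]
    n_controls: int = 9
    tracking: TrackingParams = field(default_factory=TrackingParams)
    visc: ViscParams = field(default_factory=ViscParams)
    alpha: float = 0.05
    tails: dict = field(default_factory=lambda: dict(DEFAULT_TAILS))
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        ph = dict(d.pop("phantom"))
        ph["shape"] = tuple(ph["shape"])
        ph["voxel_size"] = tuple(ph.get("voxel_size", (1.0, 1.0, 1.0)))
        bundles = []
        for b in ph.get("bundles", ()):  # dicts or BundleSpec
            if isinstance(b, BundleSpec):
                bundles.append(b)
            else:
                b = dict(b)
                b["centerline"] = tuple(tuple(p) for p in b["centerline"])
                b["eigenvalues"] = tuple(b.get("eigenvalues", (1.7e-3, 0.3e-3, 0.3e-3)))
                bundles.append(BundleSpec(**b))
        ph["bundles"] = tuple(bundles)
        if ph.get("lesion"):
            ph["lesion"] = _lesion_from(ph["lesion"])
        else:
            ph["lesion"] = None
        subjects = []
        for s in d.pop("subjects"):
            if isinstance(s, SubjectSpec):
                subjects.append(s)
            else:
                subjects.append(
                    SubjectSpec(
                        lesion=_lesion_from(s["lesion"]),
                        fm_score=float(s["fm_score"]),
                        name=s.get("name", ""),
                    )
                )
        tracking = d.pop("tracking", {})
        visc = d.pop("visc", {})
        return cls(
            phantom=PhantomSpec(**ph),
            subjects=subjects,
            tracking=tracking if isinstance(tracking, TrackingParams) else TrackingParams(**tracking),
            visc=visc if isinstance(visc, ViscParams) else ViscParams(**visc),
            **d,
        )


def _lesion_from(obj) -> LesionSpec:
    if isinstance(obj, LesionSpec):
        return obj
    obj = dict(obj)
    obj["center_vox"] = tuple(obj["center_vox"])
    size = obj["size_vox"]
    obj["size_vox"] = tuple(size) if isinstance(size, (list, tuple)) else float(size)
    return LesionSpec(**obj)


def metric_maps_for_field(
    tfield: TensorField,
    tracking: TrackingParams,
    visc_params: ViscParams,
) -> dict[str, np.ndarray]:
    """FA, MD and VISC maps for one tensor field (deterministic)."""
    grid = VoxelGrid(tfield.shape, tfield.voxel_size)
    fa = compute_fa(tfield)
    md = compute_md(tfield)
    seeds = generate_seeds(fa, tracking)
    if seeds.shape[0]:
        fibers = filter_fibers(track_all(seeds, tfield, fa, tracking), tracking)
        visc = compute_visc(build_direct(fibers, grid), visc_params)
        visc_values = visc.values
    else:
        visc_values = np.zeros(tfield.shape)
    return {"FA": fa.values, "MD": md.values, "VISC": visc_values}


def _realize(spec: PhantomSpec, lesion, gradient_table, seed: int) -> TensorField:
    from dataclasses import replace

    tfield, _ = generate_phantom(replace(spec, lesion=lesion))
    if spec.noise_sigma == 0:
        return tfield
    dwi = synthesize_dwi(
        tfield, gradient_table, noise_sigma=spec.noise_sigma, seed=seed
    )
    return fit_tensor(dwi)


def run_pipeline(config: PipelineConfig, outdir=None) -> dict:
    """Execute the full study on a phantom cohort.

    Stages (each logged with timing): cohort synthesis, tensor maps and
    tractography per brain, per-subject voxel-wise t-tests for each metric,
    LDV table, and LDV-vs-score simple regressions (when >= 3 subjects).
    Returns a result bundle; writes intermediates under ``outdir`` if given.
    """
    t0 = time.time()
    rng_seq = np.random.SeedSequence(config.seed)
    n_brains = config.n_controls + len(config.subjects)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in rng_seq.spawn(n_brains)]
    gradient_table = uniform_gradient_directions()

    def stage(name):
        logger.info("stage %-12s t=%.1fs", name, time.time() - t0)

    stage("cohort")
    control_maps: dict[str, list[np.ndarray]] = {m: [] for m in DEFAULT_TAILS}
    for i in range(config.n_controls):
        tf = _realize(config.phantom, None, gradient_table, seeds[i])
        maps = metric_maps_for_field(tf, config.tracking, config.visc)
        for m, arr in maps.items():
            control_maps[m].append(arr)

    stage("subjects")
    records = []
    subject_maps: dict[str, list[np.ndarray]] = {m: [] for m in DEFAULT_TAILS}
    sig_masks: dict[str, list[np.ndarray]] = {m: [] for m in DEFAULT_TAILS}
    for j, subj in enumerate(config.subjects):
        tf = _realize(
            config.phantom, subj.lesion, gradient_table, seeds[config.n_controls + j]
        )
        maps = metric_maps_for_field(tf, config.tracking, config.visc)
        row = {"subject": subj.name or f"S{j:02d}", "fm_score": subj.fm_score}
        for m in DEFAULT_TAILS:
            res = voxelwise_ttest(
                maps[m], control_maps[m], tail=config.tails[m], alpha=config.alpha
            )
            count = difference_volume(res.significant)
            row[f"count_{m}"] = count
            row[f"ldv_{m}"] = ldv(count)
            subject_maps[m].append(maps[m])
            sig_masks[m].append(res.significant)
        records.append(row)
    ldv_table = pd.DataFrame.from_records(records)

    stage("regression")
    regressions = {}
    if len(config.subjects) >= 3:
        scores = ldv_table["fm_score"].to_numpy()
        for m in DEFAULT_TAILS:
            x = ldv_table[f"ldv_{m}"].to_numpy()
            try:
                reg = simple_regression(x, scores)
                regressions[m] = {
                    "r_squared": reg.r_squared,
                    "p_value": reg.p_value,
                    "slope": float(reg.coef[1]),
                    "n": reg.n,
                }
            except ValueError as err:
                regressions[m] = {"error": str(err)}

    result = {
        "ldv_table": ldv_table,
        "regressions": regressions,
        "control_maps": control_maps,
        "subject_maps": subject_maps,
        "sig_masks": sig_masks,
        "config": config,
    }

    if outdir is not None:
        from pathlib import Path

        import nibabel as nib

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        affine = np.diag(list(config.phantom.voxel_size) + [1.0])
        for m in DEFAULT_TAILS:
            for j, arr in enumerate(subject_maps[m]):
                nib.save(nib.Nifti1Image(arr, affine), out / f"sub{j:02d}_{m}.nii.gz")
                nib.save(
                    nib.Nifti1Image(sig_masks[m][j].astype(np.uint8), affine),
                    out / f"sub{j:02d}_{m}_sig.nii.gz",
                )
        ldv_table.to_csv(out / "ldv_table.tsv", sep="\t", index=False)
        (out / "regressions.json").write_text(json.dumps(regressions, indent=2))
        (out / "config.json").write_text(json.dumps(config.to_dict(), indent=2, default=list))
    stage("done")
    return result
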