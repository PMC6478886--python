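"""Mass-univariate execution: the partitioned ANOVA at every voxel.

One NIfTI volume per subject per within-subject cell is stacked into an
observations x voxels matrix; design matrices, averaging operators and
contrast quadratic forms are computed once and applied to all voxels
simultaneously.  Outputs are per-effect F, p and (optionally) FDR-adjusted
p and per-voxel sphericity-epsilon maps.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import helmert

from .design import DesignSpec, ModelTerm
from .fitting import PlanFitter
from .errors import PartGLMError

__all__ = [
    "VoxelDataset",
    "VoxelResults",
    "load_image_stack",
    "write_observation_images",
    "run_voxelwise",
    "write_stat_maps",
]

logger = logging.getLogger("partglm")


@dataclass
class VoxelDataset:
    """Masked responses with provenance.

    ``responses`` is observations x in-mask voxels, row ``i`` matching row
    ``i`` of the observation table ``obs`` (subject + factor levels).
    """

    responses: np.ndarray
    obs: pd.DataFrame
    mask: np.ndarray
    affine: np.ndarray
    shape: tuple

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.responses.shape[0] != len(self.obs):
            raise ValueError("responses rows must match the observation table")
        if self.responses.shape[1] != int(self.mask.sum()):
            raise ValueError("responses columns must match the mask size")

    @property
    def n_voxels(self) -> int:
        return self.responses.shape[1]

    def volume(self, values: np.ndarray, fill=np.nan) -> np.ndarray:
        out = np.full(self.shape, fill, dtype=float)
        out[self.mask] = values
        return out


def load_image_stack(paths, obs: pd.DataFrame, mask=None) -> VoxelDataset:
    """Stack per-observation 3-D volumes into a :class:`VoxelDataset`.

    ``paths`` must align 1:1 with the rows of ``obs``.  All images must
    share shape and affine; voxels that are non-finite in any image are
    removed from the mask with a warning.
    """
    paths = [Path(p) for p in paths]
    if len(paths) != len(obs):
        raise ValueError("one image per observation-table row is required")
    first = nib.load(str(paths[0]))
    shape, affine = first.shape, first.affine
    data = np.empty((len(paths),) + shape)
    for i, p in enumerate(paths):
        img = nib.load(str(p))
        if img.shape != shape or not np.allclose(img.affine, affine, atol=1e-6):
            raise PartGLMError(
                f"image {p} geometry (shape/affine) differs from {paths[0]}"
            )
        data[i] = np.asanyarray(img.dataobj, dtype=float)
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != shape:
            raise PartGLMError("mask shape differs from the images")
    finite = np.isfinite(data).all(axis=0)
    dropped = int((mask & ~finite).sum())
    if dropped:
        logger.warning("masking %d voxel(s) with non-finite values", dropped)
    mask = mask & finite
    return VoxelDataset(
        responses=data[:, mask],
        obs=obs.reset_index(drop=True),
        mask=mask,
        affine=np.asarray(affine, dtype=float),
        shape=shape,
    )


def write_observation_images(vd: VoxelDataset, out_dir) -> list:
    """Write one 3-D NIfTI per observation (the inverse of
    :func:`load_image_stack`); returns the file paths in row order."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i in range(len(vd.obs)):
        vol = vd.volume(vd.responses[i], fill=0.0)
        p = out_dir / f"obs_{i:04d}.nii.gz"
        nib.save(nib.Nifti1Image(vol.astype(np.float32), vd.affine), str(p))
        paths.append(p)
    return paths


@dataclass
class VoxelResults:
    """Per-effect statistic vectors over the in-mask voxels."""

    dataset: VoxelDataset
    design: DesignSpec
    effects: dict          # label -> {"F","p",("p_fdr"),("epsilon"),...}
    dfmap: dict            # label -> (df_num, df_den)
    correction: str
    plan_summary: list

    def volume(self, effect: str, stat: str) -> np.ndarray:
        return self.dataset.volume(self.effects[effect][stat])


def _per_voxel_epsilon(vd: VoxelDataset, design: DesignSpec, V, method):
    """Vectorised per-voxel Greenhouse-Geisser / Huynh-Feldt epsilon for
    the stratum spanned by within factors ``V``."""
    unit = design.unit_factor.name
    withins = [f.name for f in design.within_factors]
    levels = [int(design.factor(w).n_levels) for w in withins]
    mats = []
    for w, lv in zip(withins, levels):
        mats.append(helmert(lv, full=False) if w in V
                    else np.full((1, lv), 1.0 / lv))
    M = np.array([[1.0]])
    for m in reversed(mats):
        M = np.kron(M, m)
    d = M.shape[0]

    obs = vd.obs
    stride, cell = 1, np.zeros(len(obs), dtype=int)
    for w, lv in zip(withins, levels):
        cell += (obs[w].to_numpy() - 1) * stride
        stride *= lv
    subj_ids, subj_code = np.unique(obs[unit].to_numpy(), return_inverse=True)
    n_subj = len(subj_ids)
    arr = np.empty((n_subj, stride, vd.n_voxels))
    arr[subj_code, cell] = vd.responses
    Z = np.einsum("dm,smv->dsv", M, arr)

    betweens = [f.name for f in design.between_factors]
    if betweens:
        ginfo = obs.drop_duplicates(subset=[unit]).set_index(unit)
        glab = ginfo.loc[subj_ids][betweens].apply(tuple, axis=1).to_numpy()
    else:
        glab = np.array([0] * n_subj)
    uniq = pd.unique(glab)
    g = len(uniq)
    for u in uniq:
        sel = glab == u
        Z[:, sel, :] -= Z[:, sel, :].mean(axis=1, keepdims=True)
    ne = n_subj - g
    S = np.einsum("isv,jsv->ijv", Z, Z) / ne
    tr = np.einsum("iiv->v", S)
    tr2 = np.einsum("ijv,jiv->v", S, S)
    with np.errstate(divide="ignore", invalid="ignore"):
        gg = tr ** 2 / (d * tr2)
    if d == 1 or method == "gg":
        eps = np.where(d == 1, 1.0, gg)
    else:
        num = (n_subj - g + 1) * d * gg - 2.0
        den = d * (ne - d * gg)
        hf = np.where(den > 0, num / den, 1.0)
        eps = np.minimum(hf, 1.0)
    return np.clip(eps, 1.0 / d, 1.0)


def run_voxelwise(
    vd: VoxelDataset,
    design: DesignSpec,
    coding: str = "overparameterized",
    correction: str = "none",
    fdr: float | None = None,
) -> VoxelResults:
    """Partitioned ANOVA at every in-mask voxel.

    ``correction`` (``"none"``/``"gg"``/``"hf"``) applies per-voxel
    sphericity-epsilon df adjustment to within-subject tests; ``fdr`` adds
    Benjamini-Hochberg-adjusted p-values across in-mask voxels per effect.
    """
    fitter = PlanFitter(design, obs=vd.obs, coding=coding)
    res = fitter.analyze(vd.responses)
    withins_all = tuple(f.name for f in design.within_factors)
    eps_cache: dict[tuple, np.ndarray] = {}
    effects, dfmap = {}, {}
    for row in res.effects:
        label = row["label"]
        out = {"F": row["F"], "p": row["p"]}
        d1, d2 = row["df"], row["error_df"]
        entry = row["entry"]
        stratum = entry.error_term
        if correction in ("gg", "hf") and stratum.kind != "fixed":
            V = tuple(w for w in withins_all if w in stratum.subscripts)
            if stratum.kind == "residual":
                V = withins_all
            if V:
                if V not in eps_cache:
                    eps_cache[V] = _per_voxel_epsilon(vd, design, V, correction)
                eps = eps_cache[V]
                out["epsilon"] = eps
                out["p"] = stats.f.sf(out["F"], d1 * eps, d2 * eps)
        if fdr is not None:
            from statsmodels.stats.multitest import multipletests

            finite = np.isfinite(out["p"])
            padj = np.full_like(out["p"], np.nan)
            if finite.any():
                padj[finite] = multipletests(
                    out["p"][finite], alpha=fdr, method="fdr_bh"
                )[1]
            out["p_fdr"] = padj
        effects[label] = out
        dfmap[label] = (d1, d2)
    plan_summary = [
        {
            "error_term": e.label,
            "average_over": list(e.average_over),
            "effects": [t.label for t in e.effects_tested],
            "df_error": int(e.df_error),
        }
        for e in fitter.plan.entries
    ]
    return VoxelResults(
        dataset=vd,
        design=design,
        effects=effects,
        dfmap=dfmap,
        correction=correction,
        plan_summary=plan_summary,
    )


def _safe(label: str) -> str:
    return re.sub(r"[^A-Za-z0-9]+", "_", label).strip("_")


def write_stat_maps(results: VoxelResults, out_dir) -> list:
    """One volume per effect per statistic (``<effect>_<stat>.nii.gz``)
    plus a JSON sidecar with the design, plan and degrees of freedom."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    vd = results.dataset
    written = []
    for label, stats_ in results.effects.items():
        for stat, values in stats_.items():
            vol = vd.volume(values).astype(np.float32)
            path = out_dir / f"{_safe(label)}_{stat}.nii.gz"
            nib.save(nib.Nifti1Image(vol, vd.affine), str(path))
            written.append(path)
    sidecar = {
        "software": "partglm",
        "version": __version__,
        "correction": results.correction,
        "design": {
            "factors": [
                {
                    "name": f.name,
                    "levels": int(f.n_levels),
                    "kind": f.kind,
                    "scope": f.scope,
                    "nested_in": list(f.nested_in),
                }
                for f in results.design.factors
            ],
            "group_sizes": list(results.design.group_sizes or []),
        },
        "plan": results.plan_summary,
        "df": {k: [float(a), float(b)] for k, (a, b) in results.dfmap.items()},
    }
    spath = out_dir / "analysis.json"
    with open(spath, "w") as fh:
        json.dump(sidecar, fh, indent=2)
    written.append(spath)
    return written
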