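"""Synthetic data with the exact variance-component structure of
mixed-measures ANOVA models.

Responses are built by summing the grand mean, fixed cell effects, a
Gaussian subject effect, Gaussian subject-by-within-factor effects (one
per error stratum) and residual noise:

    y_ijkl = mu + (fixed cell effects) + S_l(k) + (S*A)_il(k)
             + (S*B)_jl(k) + eps_ijkl

with S ~ N(0, sigma_s^2), (S*W) ~ N(0, sigma_sW^2) and
eps ~ N(0, sigma^2).  Subject-by-within interaction effects follow the
restricted mixed-model convention (each subject's effects sum to zero
over the fixed factor's levels; sigma_sW^2 is the variance parameter of
that convention), matching the tabular EMS derivation the engine uses.
The
``compound_symmetric`` and ``ar1`` covariance modes instead draw each
subject's within-cell noise vector from the corresponding structured
covariance, to exercise the sphericity module; ``spherical`` is the
variance-component construction above.

All randomness flows through one seeded generator; the same seed yields
byte-identical data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .contrasts import canonical_observation_table
from .design import CovariateSpec, DesignSpec
from .ems import compute_df, derive_ems
from .fitting import LongDataset, PlanFitter

__all__ = [
    "CovariateModel",
    "SimulationSpec",
    "simulate_dataset",
    "simulate_images",
    "monte_carlo_ems_check",
]


@dataclass
class CovariateModel:
    """Covariate generation: raw values ~ N(mean, sd^2) per measurement
    unit, entering the response through stratum-matched slopes.

    ``slopes`` keys: ``"mean"`` (per-subject average), a within factor
    name (per-level subject average), or ``"raw"``.
    """

    slopes: dict = field(default_factory=dict)
    sd: float = 1.0
    mean: float = 0.0


@dataclass
class SimulationSpec:
    """Ground truth for a simulated dataset.

    ``effects`` maps ``"Factor"`` or ``"Factor:Other"`` keys to arrays of
    fixed effects (indexed by 0-based levels) that sum to zero along every
    axis.  ``variances`` uses keys ``"sigma2"`` (residual), ``"sigma2_s"``
    (subject) and ``"sigma2_s:<Within>"`` (subject-by-within strata).
    """

    design: DesignSpec
    mu: float = 0.0
    effects: dict = field(default_factory=dict)
    variances: dict = field(default_factory=lambda: {"sigma2": 1.0})
    covariance: str = "spherical"  # spherical | compound_symmetric | ar1
    rho: float = 0.0
    covariate: CovariateModel | None = None
    seed: int = 0

    def __post_init__(self):
        for key, arr in self.effects.items():
            arr = np.asarray(arr, dtype=float)
            self.effects[key] = arr
            names = key.split(":")
            if arr.ndim != len(names):
                raise ValueError(f"effect {key!r} needs a {len(names)}-d array")
            for ax, name in enumerate(names):
                if int(self.design.factor(name).n_levels) != arr.shape[ax]:
                    raise ValueError(f"effect {key!r} axis {ax} level mismatch")
                if np.abs(arr.sum(axis=ax)).max() > 1e-8:
                    raise ValueError(
                        f"effect {key!r} must sum to zero over {name!r}"
                    )
        if self.covariance not in ("spherical", "compound_symmetric", "ar1"):
            raise ValueError(f"unknown covariance mode {self.covariance!r}")

    @classmethod
    def from_dict(cls, cfg: dict) -> "SimulationSpec":
        """Build from a plain config mapping (the YAML dialect): keys
        ``design`` (see :meth:`DesignSpec.from_dict`), ``mu``, ``effects``,
        ``variances``, ``covariance``, ``rho``, ``covariate`` (``slopes``,
        ``sd``, ``mean``) and ``seed``."""
        cov = cfg.get("covariate")
        return cls(
            design=DesignSpec.from_dict(cfg["design"]),
            mu=float(cfg.get("mu", 0.0)),
            effects={k: np.asarray(v, float) for k, v in cfg.get("effects", {}).items()},
            variances={k: float(v) for k, v in cfg.get("variances", {"sigma2": 1.0}).items()},
            covariance=cfg.get("covariance", "spherical"),
            rho=float(cfg.get("rho", 0.0)),
            covariate=CovariateModel(**cov) if cov else None,
            seed=int(cfg.get("seed", 0)),
        )

    def stratum_variance(self, withins: tuple) -> float:
        key = "sigma2_s" + "".join(f":{w}" for w in withins)
        return float(self.variances.get(key, 0.0))


def _fixed_cell_values(spec: SimulationSpec, obs: pd.DataFrame) -> np.ndarray:
    y = np.full(len(obs), float(spec.mu))
    for key, arr in spec.effects.items():
        names = key.split(":")
        idx = tuple(obs[n].to_numpy() - 1 for n in names)
        y = y + arr[idx]
    return y


def _within_cell_index(design: DesignSpec, obs: pd.DataFrame):
    withins = [f.name for f in design.within_factors]
    m, idx = 1, np.zeros(len(obs), dtype=int)
    for w in withins:
        lv = int(design.factor(w).n_levels)
        idx += (obs[w].to_numpy() - 1) * m
        m *= lv
    return idx, m


def _structured_cov(mode: str, m: int, sigma2: float, rho: float) -> np.ndarray:
    if mode == "compound_symmetric":
        R = np.full((m, m), rho)
        np.fill_diagonal(R, 1.0)
    else:  # ar1 over the flattened within-cell index
        i = np.arange(m)
        R = rho ** np.abs(i[:, None] - i[None, :])
    return sigma2 * R


def _noise_matrix(spec: SimulationSpec, obs: pd.DataFrame, n_cols: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Random part of the response, one independent replicate per column."""
    design = spec.design
    unit = design.unit_factor
    n = len(obs)
    out = np.zeros((n, n_cols))
    if unit is None:
        out += rng.normal(
            0.0, np.sqrt(spec.variances.get("sigma2", 0.0)), size=(n, n_cols)
        )
        return out
    subj = obs[unit.name].to_numpy()
    subj_ids, subj_code = np.unique(subj, return_inverse=True)
    n_subj = len(subj_ids)
    s2 = float(spec.variances.get("sigma2_s", 0.0))
    draws = rng.normal(0.0, np.sqrt(s2), size=(n_subj, n_cols))
    out += draws[subj_code]
    withins = [f.name for f in design.within_factors]
    if spec.covariance == "spherical":
        for size in range(1, len(withins)):
            for V in combinations(withins, size):
                v2 = spec.stratum_variance(V)
                if v2 == 0.0:
                    continue
                # restricted mixed-model draws: each subject's interaction
                # effects sum to zero over the fixed within levels (v2 is
                # the variance parameter of the tabular EMS convention)
                levels = [int(design.factor(w).n_levels) for w in V]
                D = rng.normal(0.0, np.sqrt(v2),
                               size=(n_subj, *levels, n_cols))
                for ax in range(1, 1 + len(V)):
                    D = D - D.mean(axis=ax, keepdims=True)
                idx = (subj_code,) + tuple(
                    obs[w].to_numpy() - 1 for w in V)
                out += D[idx]
        out += rng.normal(
            0.0, np.sqrt(spec.variances.get("sigma2", 0.0)), size=(n, n_cols)
        )
    else:
        cell, m = _within_cell_index(design, obs)
        cov = _structured_cov(
            spec.covariance, m, float(spec.variances.get("sigma2", 1.0)),
            float(spec.rho),
        )
        chol = np.linalg.cholesky(cov + 1e-12 * np.eye(m))
        z = rng.standard_normal(size=(n_subj, m, n_cols))
        e = np.einsum("ij,sjc->sic", chol, z)
        out += e[subj_code, cell]
    return out


def _covariate_frame(spec: SimulationSpec, obs: pd.DataFrame,
                     rng: np.random.Generator):
    """Raw covariate values and their contribution to the response."""
    design = spec.design
    cm = spec.covariate
    unit = design.unit_factor.name
    cols = {}
    signal = np.zeros(len(obs))
    for cov in design.covariates:
        keys = [unit] + list(cov.varies_over)
        gid = obs.groupby(keys, sort=False).ngroup().to_numpy()
        vals = rng.normal(cm.mean, cm.sd, size=gid.max() + 1)[gid]
        cols[cov.name] = vals
        work = obs.assign(__x=vals)
        for skey, slope in cm.slopes.items():
            if skey == "mean":
                col = work.groupby(unit, sort=False)["__x"].transform("mean")
            elif skey == "raw":
                col = work["__x"]
            else:
                col = work.groupby([unit, skey], sort=False)["__x"].transform("mean")
            signal = signal + slope * col.to_numpy()
    return cols, signal


def simulate_dataset(spec: SimulationSpec, voxel: int = 0) -> LongDataset:
    """One long-format dataset; ``(seed, voxel)`` fixes the random stream."""
    design = spec.design
    obs = canonical_observation_table(design)
    rng = np.random.default_rng([int(spec.seed), int(voxel)])
    y = _fixed_cell_values(spec, obs) + _noise_matrix(spec, obs, 1, rng)[:, 0]
    frame = obs.copy()
    if design.covariates:
        if spec.covariate is None:
            raise ValueError("design declares covariates but the simulation "
                             "spec has no covariate model")
        cols, signal = _covariate_frame(spec, obs, rng)
        for name, vals in cols.items():
            frame[name] = vals
        y = y + signal
    frame["value"] = y
    return LongDataset(frame=frame, design=design)


def simulate_response_matrix(
    spec: SimulationSpec, n_cols: int, seed_offset: int = 0
) -> tuple:
    """(observation table, response matrix) with independent replicate
    columns -- the fast path for Monte-Carlo work."""
    design = spec.design
    obs = canonical_observation_table(design)
    rng = np.random.default_rng([int(spec.seed), 2 ** 31 + int(seed_offset)])
    Y = _fixed_cell_values(spec, obs)[:, None] + _noise_matrix(
        spec, obs, n_cols, rng
    )
    return obs, Y


def simulate_images(spec: SimulationSpec, shape, effect_mask=None):
    """Independent voxel simulations as a :class:`~partglm.voxelwise.VoxelDataset`.

    Fixed effects are injected only inside ``effect_mask``; voxel ``v``
    of the stack reproduces ``simulate_dataset(spec, voxel=v)`` exactly
    (when the voxel carries the effects).
    """
    from .voxelwise import VoxelDataset

    design = spec.design
    shape = tuple(shape)
    n_vox = int(np.prod(shape))
    if effect_mask is None:
        effect_mask = np.ones(shape, dtype=bool)
    effect_mask = np.asarray(effect_mask, dtype=bool).reshape(shape)
    obs = canonical_observation_table(design)
    fixed = _fixed_cell_values(spec, obs)
    null_spec_fixed = np.full(len(obs), float(spec.mu))
    Y = np.empty((len(obs), n_vox))
    flat_mask = effect_mask.ravel()
    for v in range(n_vox):
        rng = np.random.default_rng([int(spec.seed), v])
        noise = _noise_matrix(spec, obs, 1, rng)[:, 0]
        Y[:, v] = (fixed if flat_mask[v] else null_spec_fixed) + noise
    return VoxelDataset(
        responses=Y,
        obs=obs,
        mask=np.ones(shape, dtype=bool),
        affine=np.eye(4),
        shape=shape,
    )


def monte_carlo_ems_check(spec: SimulationSpec, n_reps: int = 2000) -> pd.DataFrame:
    """Empirical mean of every mean square vs. its EMS prediction.

    Simulates ``n_reps`` datasets, runs the partitioned pipeline on all of
    them at once, rescales each sub-model's sums of squares back to the
    full-model scale (the product of the averaged level counts), and
    compares the empirical mean of each mean square with the numeric value
    of its EMS row.  The keystone cross-module validation: the simulator,
    the EMS engine and the fitting pipeline must agree.
    """
    if spec.covariance != "spherical":
        raise ValueError("EMS recovery requires the spherical (variance "
                         "component) covariance mode")
    design = spec.design
    ems = derive_ems(design)
    obs, Y = simulate_response_matrix(spec, n_reps)
    fitter = PlanFitter(design, obs=obs)
    res = fitter.analyze(Y)

    components = {"sigma2": float(spec.variances.get("sigma2", 0.0))}
    unit = design.unit_factor
    withins = [f.name for f in design.within_factors]
    for t in ems.terms:
        if t.is_random and not t.is_error and unit and unit.name in t.factors:
            V = tuple(w for w in withins if w in t.factors)
            components[t.component_name] = spec.stratum_variance(V)
    dfmap = compute_df(design)
    for key, arr in spec.effects.items():
        names = tuple(key.split(":"))
        term = next(t for t in ems.terms
                    if t.kind == "fixed" and set(t.factors) == set(names))
        components[term.component_name] = float(
            (arr ** 2).sum() / dfmap[term]
        )

    rows = []

    def add(term, ms_samples):
        mean = float(np.mean(ms_samples))
        se = float(np.std(ms_samples, ddof=1) / np.sqrt(len(ms_samples)))
        rows.append(
            {
                "Term": term.label,
                "MeanMS": mean,
                "PredictedEMS": ems.evaluate(term, components),
                "SE": se,
                "n_reps": len(ms_samples),
            }
        )

    for r in res.effects:
        if r["is_covariate"]:
            continue
        add(r["effect"], r["SS"] * r["scale"] / r["df"])
    for ent in res.entries:
        add(ent["entry"].error_term, ent["rss"] * ent["scale"] / ent["df"])
    return pd.DataFrame(rows)
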