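"""Synthetic twin cohorts, attention-task sessions, and tract phantoms.

These generators produce inputs with the statistical structure the analysis
stages assume, so every downstream operation can be tested against known
ground truth without any imaging or behavioral data download:

* :func:`gen_twin_cohort` draws bivariate twin phenotypes from a standardized
  ACE generative model (additive genetic A, shared environment C, unique
  environment E) with chosen path coefficients and cross-trait latent
  correlations.  Latent A correlates 1.0 within monozygotic (MZ) and 0.5
  within dizygotic (DZ) pairs, C correlates 1.0 within both, E is twin
  specific.
* :func:`gen_ant_session` simulates an Attention Network Test session — six
  blocks of thirty-six trials crossing cue (none / center / spatial) with
  flanker congruency — with per-cell mean reaction times, multiplicative
  log-normal RT noise, per-cell error rates, and a 2000 ms response deadline.
* :func:`gen_tract_phantom` builds a tract phantom: smooth streamlines that
  traverse five axis-aligned lobar label slabs in order, with FA and MD
  volumes whose per-slab means are known exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tract import LabelVolume, ScalarVolume, Tractogram

__all__ = [
    "AceGenParams",
    "AntGenParams",
    "PhantomSpec",
    "gen_twin_cohort",
    "gen_ant_session",
    "gen_tract_phantom",
    "expected_scores",
    "CUE_LEVELS",
    "FLANKER_LEVELS",
]

CUE_LEVELS = ("none", "center", "spatial")
FLANKER_LEVELS = ("congruent", "incongruent")

# Default per-cell mean RTs (ms).  Additive cue/flanker structure chosen so a
# noiseless session yields ratio scores of the magnitude reported for healthy
# adolescent cohorts (alerting ~0.06, orienting ~0.09, EC ~0.17 at an overall
# mean RT of 600 ms).
_DEFAULT_CELL_MEANS = {
    ("none", "congruent"): 592.0,
    ("none", "incongruent"): 692.0,
    ("center", "congruent"): 556.0,
    ("center", "incongruent"): 656.0,
    ("spatial", "congruent"): 502.0,
    ("spatial", "incongruent"): 602.0,
}


# ---------------------------------------------------------------------------
# twin cohort generator
# ---------------------------------------------------------------------------

@dataclass
class AceGenParams:
    """Generative parameters of the (bivariate) standardized ACE twin model.

    ``a1, c1, e1`` are path coefficients for trait 1 (a1**2 + c1**2 + e1**2
    must equal 1 so the trait is standardized); ``a2, c2, e2`` likewise for
    trait 2 and may be left ``None`` for a univariate cohort.  ``rg, rc, re``
    are the cross-trait correlations of the latent A, C, and E factors.
    Pair counts default to the classical small twin design of 14 MZ and 16 DZ
    pairs; simulations scale them up explicitly.
    """

    a1: float
    c1: float
    e1: float
    a2: float | None = None
    c2: float | None = None
    e2: float | None = None
    rg: float = 0.0
    rc: float = 0.0
    re: float = 0.0
    n_mz: int = 14
    n_dz: int = 16
    seed: int = 0

    @property
    def bivariate(self) -> bool:
        return self.a2 is not None

    def validate(self) -> None:
        for name, (a, c, e) in {"trait 1": (self.a1, self.c1, self.e1),
                                "trait 2": (self.a2, self.c2, self.e2)}.items():
            if a is None:
                continue
            if c is None or e is None:
                raise ValueError(f"incomplete path coefficients for {name}")
            tot = a * a + c * c + e * e
            if abs(tot - 1.0) > 1e-6:
                raise ValueError(
                    f"{name} paths are not standardized: a^2+c^2+e^2 = {tot:.6f}")
        for name, r in (("rg", self.rg), ("rc", self.rc), ("re", self.re)):
            if abs(r) > 1.0:
                raise ValueError(f"|{name}| must be <= 1, got {r}")
        if self.n_mz < 0 or self.n_dz < 0:
            raise ValueError("pair counts must be non-negative")


def _component_block(p1: float, p2: float | None, r: float) -> np.ndarray:
    """Cross-trait covariance contributed by one latent component."""
    if p2 is None:
        return np.array([[p1 * p1]])
    return np.array([[p1 * p1, r * p1 * p2],
                     [r * p1 * p2, p2 * p2]])


def twin_pair_covariance(params: AceGenParams, zygosity: str) -> np.ndarray:
    """Model-implied covariance of the observed phenotypes of one twin pair.

    Variable order is (trait1 twin1, [trait2 twin1,] trait1 twin2,
    [trait2 twin2]).
    """
    r_a = 1.0 if zygosity == "MZ" else 0.5
    sig_a = _component_block(params.a1, params.a2, params.rg)
    sig_c = _component_block(params.c1, params.c2, params.rc)
    sig_e = _component_block(params.e1, params.e2, params.re)
    within = sig_a + sig_c + sig_e
    cross = r_a * sig_a + sig_c
    top = np.hstack([within, cross])
    bot = np.hstack([cross, within])
    sigma = np.vstack([top, bot])
    evals = np.linalg.eigvalsh(sigma)
    if evals.min() < -1e-9:
        raise ValueError(
            f"assembled {zygosity} pair covariance is not positive "
            f"semidefinite (min eigenvalue {evals.min():.3e}); check the "
            f"rg/rc/re cross-trait correlation block")
    return sigma


def gen_twin_cohort(params: AceGenParams) -> pd.DataFrame:
    """Draw a twin cohort from the ACE generative model.

    Returns a table with one row per pair: ``pair_id``, ``zygosity``, and
    trait columns ``trait1_twin1, trait1_twin2[, trait2_twin1,
    trait2_twin2]``.  Each trait has unit variance in expectation.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    k = 2 if params.bivariate else 1
    rows = []
    for zyg, n in (("MZ", params.n_mz), ("DZ", params.n_dz)):
        sigma = twin_pair_covariance(params, zyg)
        draws = rng.multivariate_normal(np.zeros(2 * k), sigma, size=n,
                                        method="svd")
        for j in range(n):
            row = {"pair_id": f"{zyg}{j + 1:04d}", "zygosity": zyg,
                   "trait1_twin1": draws[j, 0], "trait1_twin2": draws[j, k]}
            if k == 2:
                row["trait2_twin1"] = draws[j, 1]
                row["trait2_twin2"] = draws[j, 3]
            rows.append(row)
    cols = ["pair_id", "zygosity", "trait1_twin1", "trait1_twin2"]
    if k == 2:
        cols += ["trait2_twin1", "trait2_twin2"]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# attention-task generator
# ---------------------------------------------------------------------------

@dataclass
class AntGenParams:
    """Generative parameters for one Attention Network Test session.

    ``cell_mean_rt`` maps each (cue, flanker) cell to its mean RT in ms;
    ``rt_sd`` is the RT standard deviation in ms (log-normal multiplicative
    noise with matched mean and SD by default, Gaussian via
    ``rt_noise='normal'``); ``error_rate`` is the per-trial probability of an
    incorrect response (scalar or per-cell dict).  Responses are capped at
    the ``deadline_ms`` response window.
    """

    cell_mean_rt: dict = field(default_factory=lambda: dict(_DEFAULT_CELL_MEANS))
    rt_sd: float = 100.0
    error_rate: float | dict = 0.03
    n_blocks: int = 6
    trials_per_block: int = 36
    rt_noise: str = "lognormal"
    deadline_ms: float = 2000.0
    subject: str = "S01"
    seed: int = 0

    def cells(self) -> list[tuple[str, str]]:
        return [(c, f) for c in CUE_LEVELS for f in FLANKER_LEVELS]

    def cell_error(self, cell: tuple[str, str]) -> float:
        if isinstance(self.error_rate, dict):
            return float(self.error_rate[cell])
        return float(self.error_rate)

    def validate(self) -> None:
        cells = set(self.cells())
        if set(self.cell_mean_rt) != cells:
            raise ValueError("cell_mean_rt must cover all 3 cue x 2 flanker cells")
        if any(m <= 0 for m in self.cell_mean_rt.values()):
            raise ValueError("all cell mean RTs must be positive")
        for cell in cells:
            er = self.cell_error(cell)
            if not 0.0 <= er <= 1.0:
                raise ValueError(f"error rate for {cell} outside [0, 1]")
        if self.rt_sd < 0:
            raise ValueError("rt_sd must be non-negative")
        if self.trials_per_block % len(cells):
            raise ValueError("trials_per_block must divide evenly into 6 cells")
        if self.rt_noise not in ("lognormal", "normal"):
            raise ValueError("rt_noise must be 'lognormal' or 'normal'")


def gen_ant_session(params: AntGenParams) -> pd.DataFrame:
    """Simulate one ANT session as a trial table.

    Condition cells are balanced within each block and shuffled with the
    seed.  Returns columns ``subject, block, trial, cue, flanker, rt_ms,
    correct`` ordered by block then trial.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    cells = params.cells()
    reps = params.trials_per_block // len(cells)
    rows = []
    for b in range(1, params.n_blocks + 1):
        order = cells * reps
        rng.shuffle(order)
        for t, (cue, flank) in enumerate(order, start=1):
            mu = float(params.cell_mean_rt[(cue, flank)])
            if params.rt_sd == 0:
                rt = mu
            elif params.rt_noise == "lognormal":
                cv = params.rt_sd / mu
                s = np.sqrt(np.log1p(cv * cv))
                rt = float(rng.lognormal(np.log(mu) - 0.5 * s * s, s))
            else:
                rt = max(float(rng.normal(mu, params.rt_sd)), 0.0)
            rt = min(rt, params.deadline_ms)
            correct = bool(rng.random() >= params.cell_error((cue, flank)))
            rows.append({"subject": params.subject, "block": b, "trial": t,
                         "cue": cue, "flanker": flank, "rt_ms": rt,
                         "correct": correct})
    return pd.DataFrame(rows, columns=["subject", "block", "trial", "cue",
                                       "flanker", "rt_ms", "correct"])


def expected_scores(params: AntGenParams) -> dict:
    """Closed-form ratio scores implied by the generating cell means.

    Valid for balanced designs: cue means pool the two flanker cells, flanker
    means pool the three cue cells, and the denominator is the overall mean.
    """
    m = params.cell_mean_rt
    cue_mean = {c: np.mean([m[(c, f)] for f in FLANKER_LEVELS]) for c in CUE_LEVELS}
    fl_mean = {f: np.mean([m[(c, f)] for c in CUE_LEVELS]) for f in FLANKER_LEVELS}
    overall = np.mean(list(m.values()))
    return {
        "alerting": (cue_mean["none"] - cue_mean["center"]) / overall,
        "orienting": (cue_mean["center"] - cue_mean["spatial"]) / overall,
        "ec": (fl_mean["incongruent"] - fl_mean["congruent"]) / overall,
        "mean_rt": overall,
    }


# ---------------------------------------------------------------------------
# tract phantom generator
# ---------------------------------------------------------------------------

@dataclass
class PhantomSpec:
    """Geometry and ground truth of a five-band tract phantom.

    Streamlines are smooth sinusoidal arcs spanning the first grid axis,
    which is tiled by five axis-aligned label slabs (labels 1..5, 0 reserved
    for background outside the grid).  FA and MD volumes are constant per
    slab (``band_fa`` / ``band_md``) plus optional Gaussian noise.
    """

    grid_shape: tuple = (60, 24, 24)
    voxel_size: float = 2.0
    affine: np.ndarray | None = None
    n_streamlines: int = 50
    points_per_streamline: int = 100
    band_labels: tuple = (1, 2, 3, 4, 5)
    band_fa: tuple = (0.50, 0.45, 0.40, 0.35, 0.30)
    band_md: tuple = (0.70, 0.75, 0.80, 0.85, 0.90)
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if len(self.band_labels) != 5 or len(self.band_fa) != 5 \
                or len(self.band_md) != 5:
            raise ValueError("exactly 5 label bands with FA/MD means required")
        if any(int(l) <= 0 for l in self.band_labels):
            raise ValueError("band labels must be positive integers (0 is background)")
        if len(set(self.band_labels)) != 5:
            raise ValueError("band labels must be distinct")
        if self.grid_shape[0] < 10:
            raise ValueError("grid too small along the tract axis")
        if self.n_streamlines < 1 or self.points_per_streamline < 2:
            raise ValueError("need >=1 streamline with >=2 points")

    def resolved_affine(self) -> np.ndarray:
        if self.affine is not None:
            return np.asarray(self.affine, dtype=float)
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = self.voxel_size
        # arbitrary nonzero origin so the world<->voxel map is exercised
        aff[:3, 3] = -0.5 * self.voxel_size * np.asarray(self.grid_shape)
        return aff

    def band_of_voxel_x(self, x: np.ndarray) -> np.ndarray:
        """Band index (0..4) of voxel-x coordinates; bands tile the axis."""
        nx = self.grid_shape[0]
        return np.minimum((np.asarray(x) * 5) // nx, 4).astype(int)

    def ground_truth(self) -> dict:
        return {int(l): {"fa": float(f), "md": float(m)}
                for l, f, m in zip(self.band_labels, self.band_fa, self.band_md)}


def gen_tract_phantom(spec: PhantomSpec):
    """Generate (Tractogram, FA volume, MD volume, label volume) for a phantom.

    Streamlines traverse all five label bands in order; every point lies
    inside the grid (a point escaping the grid raises, naming its index).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    nx, ny, nz = spec.grid_shape
    affine = spec.resolved_affine()

    band_idx_x = spec.band_of_voxel_x(np.arange(nx))
    labels = np.zeros(spec.grid_shape, dtype=np.int32)
    fa = np.zeros(spec.grid_shape, dtype=float)
    md = np.zeros(spec.grid_shape, dtype=float)
    for b in range(5):
        sl = band_idx_x == b
        labels[sl, :, :] = int(spec.band_labels[b])
        fa[sl, :, :] = spec.band_fa[b]
        md[sl, :, :] = spec.band_md[b]
    if spec.noise_sd > 0:
        fa = fa + rng.normal(0.0, spec.noise_sd, size=fa.shape)
        md = md + rng.normal(0.0, spec.noise_sd, size=md.shape)
    fa = np.clip(fa, 0.0, 1.0)
    md = np.clip(md, 0.0, None)

    u = np.linspace(0.0, 1.0, spec.points_per_streamline)
    cy, cz = (ny - 1) / 2.0, (nz - 1) / 2.0
    amp_max = min(ny, nz) / 5.0
    streamlines = []
    for i in range(spec.n_streamlines):
        amp = rng.uniform(-amp_max, amp_max)
        off = rng.uniform(-amp_max / 2.0, amp_max / 2.0)
        vx = 0.6 + u * (nx - 2.2)           # spans all five bands
        vy = cy + amp * np.sin(np.pi * u)
        vz = cz + off * np.ones_like(u)
        vox = np.column_stack([vx, vy, vz])
        bad = np.nonzero(~np.all((vox > -0.5) & (vox < np.array([nx, ny, nz]) - 0.5),
                                 axis=1))[0]
        if bad.size:
            raise ValueError(
                f"streamline {i} escapes the grid at point {int(bad[0])}")
        world = vox @ affine[:3, :3].T + affine[:3, 3]
        streamlines.append(world)

    tract = Tractogram(streamlines=streamlines, affine=affine,
                       shape=(nx, ny, nz),
                       voxel_size=(spec.voxel_size,) * 3)
    return (tract,
            ScalarVolume(fa, affine),
            ScalarVolume(md, affine),
            LabelVolume(labels, affine))
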