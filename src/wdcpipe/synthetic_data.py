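"""Synthetic pharmacological rs-fMRI cohorts for end-to-end pipeline testing.

The generator emulates the statistical structure of a placebo-controlled
crossover study comparing autistic and nonautistic adults (about 20 per
group), without modelling scanner physics: each session is a 4D BOLD-like
volume whose in-network voxels share a network-specific latent signal,

    x_v(t) = lam * s_k(t) + sqrt(1 - lam^2) * noise_sd * eps_v(t),

with ``s_k`` and ``eps_v`` iid standard Gaussian in time.  With the default
``noise_sd = 1`` the expected pairwise correlation between two voxels of
network ``k`` is exactly ``lam**2``, which makes connectivity effect sizes
analytically tractable.  The loading ``lam`` varies by group and condition:
the defaults encode the qualitative pattern under study — sensorimotor
connectivity reduced in the autistic group under placebo and restored by the
drug, frontoparietal connectivity slightly elevated under placebo and
nudged down by the drug — while the nonautistic group is unchanged across
conditions.  Out-of-network gray-matter voxels are pure noise.

Framewise-displacement traces are drawn from a Gamma distribution whose mean
follows group-specific targets (nonautistic 0.10 mm, autistic 0.15 mm, the
head-motion group difference that motivates the mFD covariate), and a few
sessions can be marked missing to reproduce the study's unbalanced design.

Everything is driven by one integer seed; the same seed yields a
bit-identical cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateInputError, ValidationError
from .image_io import (
    MaskVolume,
    VoxelGrid,
    write_manifest,
    write_mask,
    write_volume,
)
from .masks import NetworkMaskPair
from .motion_qc import FdTrace, write_fd_trace

GROUPS = ("nonautistic", "autistic")
CONDITIONS = ("placebo", "drug")

DEFAULT_T = 205
DEFAULT_GRID = (12, 12, 12)
DEFAULT_MFD_MEANS = {"nonautistic": 0.10, "autistic": 0.15}
DEFAULT_MFD_SDS = {"nonautistic": 0.05, "autistic": 0.08}

#: latent-signal loadings lam[(group, condition)] per network (defaults)
DEFAULT_LAMBDAS = {
    "frontoparietal": {
        ("nonautistic", "placebo"): 0.55,
        ("nonautistic", "drug"): 0.55,
        ("autistic", "placebo"): 0.62,
        ("autistic", "drug"): 0.58,
    },
    "sensorimotor": {
        ("nonautistic", "placebo"): 0.55,
        ("nonautistic", "drug"): 0.55,
        ("autistic", "placebo"): 0.42,
        ("autistic", "drug"): 0.55,
    },
}


def default_network_blocks(
    grid_shape: Sequence[int],
) -> dict[str, tuple[tuple[int, int], ...]]:
    """Two disjoint axis-aligned blocks inside the gray-matter interior.

    The interior (gray matter) is the grid minus a 1-voxel shell.  Blocks are
    kept to a few percent of the gray-matter volume, mirroring the modest
    share of the brain the real network masks occupy; each network's mean
    z-scored wDC is then only weakly coupled to the other network through
    map standardization.  The blocks are separated along x by one plane.
    """
    sx, sy, sz = (int(s) for s in grid_shape)
    if min(sx, sy, sz) < 8:
        raise ValidationError("grid must be at least 8 voxels per axis")
    wx = min(4, max(1, (sx - 5) // 2))
    wy, wz = min(4, sy - 4), min(4, sz - 4)
    y0, z0 = (sy - wy) // 2, (sz - wz) // 2
    yz = ((y0, y0 + wy), (z0, z0 + wz))
    return {
        "frontoparietal": ((2, 2 + wx),) + yz,
        "sensorimotor": ((3 + wx, 3 + 2 * wx),) + yz,
    }


def _block_size(block: tuple[tuple[int, int], ...]) -> int:
    return int(np.prod([stop - start for start, stop in block]))


@dataclass
class CohortSpec:
    """Study conditions for one synthetic cohort."""

    n_per_group: int = 20
    t_points: int = DEFAULT_T
    grid_shape: tuple[int, int, int] = DEFAULT_GRID
    voxel_size_mm: float = 3.0
    network_blocks: Mapping[str, tuple] | None = None
    lambdas: Mapping[str, Mapping[tuple[str, str], float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_LAMBDAS.items()}
    )
    noise_sd: float = 1.0
    #: out-of-network gray matter is partitioned into parcels of this many
    #: voxels, each sharing its own latent signal with a loading drawn
    #: uniformly from ``background_lambda_range``; this gives the wDC map the
    #: broad positive background distribution real gray matter shows (set
    #: ``background_parcel_size=0`` for pure-noise background)
    background_parcel_size: int = 24
    background_lambda_range: tuple[float, float] = (0.30, 0.60)
    mfd_means: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_MFD_MEANS))
    mfd_sds: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_MFD_SDS))
    #: sessions to drop, as (participant_id, condition); None selects a
    #: default emulating the study's unbalanced n (two autistic placebo and
    #: one autistic drug session missing) when the cohort is large enough
    missing_sessions: Sequence[tuple[str, str]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValidationError("need at least 2 participants per group")
        if self.t_points < 3:
            raise ValidationError("need at least 3 time points")
        if self.network_blocks is None:
            self.network_blocks = default_network_blocks(self.grid_shape)
        blocks = list(self.network_blocks.values())
        occ = np.zeros(self.grid_shape, dtype=int)
        for block in blocks:
            sl = tuple(slice(a, b) for a, b in block)
            occ[sl] += 1
        if occ.max() > 1:
            raise ValidationError("network blocks overlap")
        for net, lam_map in self.lambdas.items():
            for key, lam in lam_map.items():
                if not 0.0 <= lam <= 1.0:
                    raise ValidationError(f"lambda {lam} for {net}/{key} outside [0, 1]")
        if self.missing_sessions is None:
            if self.n_per_group >= 4:
                self.missing_sessions = (
                    ("A01", "placebo"),
                    ("A02", "placebo"),
                    ("A03", "drug"),
                )
            else:
                self.missing_sessions = ()

    @property
    def grid(self) -> VoxelGrid:
        v = self.voxel_size_mm
        affine = np.diag([v, v, v, 1.0])
        affine[:3, 3] = -v * (np.asarray(self.grid_shape) - 1) / 2.0
        return VoxelGrid(tuple(self.grid_shape), affine)

    def participant_ids(self) -> dict[str, list[str]]:
        return {
            "nonautistic": [f"N{i + 1:02d}" for i in range(self.n_per_group)],
            "autistic": [f"A{i + 1:02d}" for i in range(self.n_per_group)],
        }


@dataclass
class SessionData:
    participant_id: str
    group: str
    condition: str
    bold: np.ndarray  # 4D (x, y, z, t)
    fd: FdTrace
    mfd: float


@dataclass
class Cohort:
    spec: CohortSpec
    grid: VoxelGrid
    sessions: list[SessionData]
    gm_maps: dict[str, np.ndarray]
    mask_pair: NetworkMaskPair
    manifest: pd.DataFrame


def latent_block_timeseries(
    rng: np.random.Generator, t: int, n_voxels: int, lam: float, noise_sd: float = 1.0
) -> np.ndarray:
    """T x N series sharing one latent signal with loading ``lam``."""
    s = rng.standard_normal((t, 1))
    eps = rng.standard_normal((t, n_voxels))
    return lam * s + np.sqrt(1.0 - lam**2) * noise_sd * eps


def _interior_mask(shape: tuple[int, int, int]) -> np.ndarray:
    interior = np.zeros(shape, dtype=bool)
    interior[1:-1, 1:-1, 1:-1] = True
    return interior


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Draw a full in-memory cohort: BOLD sessions, GM maps, masks, FD, manifest."""
    rng = np.random.default_rng(spec.seed)
    grid = spec.grid
    shape = grid.shape
    t = spec.t_points
    interior = _interior_mask(shape)

    block_slices = {
        net: tuple(slice(a, b) for a, b in block)
        for net, block in spec.network_blocks.items()
    }
    net_masks = {}
    for net, sl in block_slices.items():
        memb = np.zeros(shape, dtype=bool)
        memb[sl] = True
        if not np.all(memb <= interior):
            raise ValidationError(f"network block {net} extends outside gray matter")
        net_masks[net] = MaskVolume(grid, memb, label=net)
    mask_pair = NetworkMaskPair(
        frontoparietal=net_masks["frontoparietal"],
        sensorimotor=net_masks["sensorimotor"],
    )

    ids = spec.participant_ids()
    missing = set((str(p), str(c)) for p, c in spec.missing_sessions)

    # linear (x-fastest) indices of the network blocks and background parcels
    block_lin = {net: mask.linear_indices() for net, mask in net_masks.items()}
    in_network = np.zeros(shape, dtype=bool)
    for mask in net_masks.values():
        in_network |= mask.membership
    bg_lin = MaskVolume(grid, interior & ~in_network).linear_indices()
    ps = int(spec.background_parcel_size)
    bg_parcels = [bg_lin[i : i + ps] for i in range(0, len(bg_lin), ps)] if ps > 0 else []

    gm_maps: dict[str, np.ndarray] = {}
    sessions: list[SessionData] = []
    rows = []
    n_xyz = grid.n_voxels
    lam_lo, lam_hi = spec.background_lambda_range
    for group in GROUPS:
        for pid in ids[group]:
            gm = np.full(shape, 0.10)
            gm[interior] = 0.95 + 0.04 * rng.random(int(interior.sum()))
            gm_maps[pid] = gm
            for condition in CONDITIONS:
                if (pid, condition) in missing:
                    continue
                flat = rng.standard_normal((n_xyz, t))  # voxel x time
                for net in spec.network_blocks:
                    lam = spec.lambdas[net][(group, condition)]
                    ts = latent_block_timeseries(
                        rng, t, len(block_lin[net]), lam, spec.noise_sd
                    )
                    flat[block_lin[net], :] = ts.T
                for parcel in bg_parcels:
                    lam = rng.uniform(lam_lo, lam_hi)
                    ts = latent_block_timeseries(rng, t, len(parcel), lam, spec.noise_sd)
                    flat[parcel, :] = ts.T
                bold = 800.0 + 20.0 * flat.reshape(shape + (t,), order="F")
                target = max(0.02, rng.normal(spec.mfd_means[group], spec.mfd_sds[group]))
                fd_vals = rng.gamma(shape=3.0, scale=target / 3.0, size=t)
                fd = FdTrace(fd_vals, participant_id=pid, condition=condition)
                mfd = float(fd_vals.mean())
                sessions.append(
                    SessionData(pid, group, condition, bold, fd, mfd)
                )
                rows.append(
                    {
                        "participant_id": pid,
                        "group": group,
                        "condition": condition,
                        "bold_path": "",
                        "fd_path": "",
                        "mfd": mfd,
                    }
                )
    manifest = pd.DataFrame(rows)
    return Cohort(
        spec=spec,
        grid=grid,
        sessions=sessions,
        gm_maps=gm_maps,
        mask_pair=mask_pair,
        manifest=manifest,
    )


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write a cohort to disk in the formats the pipeline reads.

    Layout: ``bold/<pid>_<condition>.nii``, ``fd/<pid>_<condition>.txt``,
    ``gm/<pid>_gm.nii``, ``masks/{frontoparietal,sensorimotor}.nii`` and
    ``manifest.tsv``.  Returns the manifest path.
    """
    out = Path(out_dir)
    for sub in ("bold", "fd", "gm", "masks"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    manifest = cohort.manifest.copy()
    for i, ses in enumerate(cohort.sessions):
        bold_path = out / "bold" / f"{ses.participant_id}_{ses.condition}.nii"
        fd_path = out / "fd" / f"{ses.participant_id}_{ses.condition}.txt"
        write_volume(bold_path, cohort.grid, ses.bold.astype(np.float32))
        write_fd_trace(fd_path, ses.fd)
        manifest.loc[i, "bold_path"] = str(bold_path)
        manifest.loc[i, "fd_path"] = str(fd_path)
    for pid, gm in cohort.gm_maps.items():
        write_volume(out / "gm" / f"{pid}_gm.nii", cohort.grid, gm.astype(np.float32))
    for net, mask in cohort.mask_pair:
        write_mask(out / "masks" / f"{net}.nii", mask)
    manifest_path = out / "manifest.tsv"
    write_manifest(manifest_path, manifest)
    return manifest_path


def expected_mean_wdc(
    spec: CohortSpec,
    group: str,
    condition: str,
    network: str,
    threshold: float = 0.25,
) -> float:
    """Delta-method expectation of pre-standardization wDC for an in-network voxel.

    Within network ``k`` the population pairwise correlation is
    rho = lam^2 / (lam^2 + (1 - lam^2) noise_sd^2) and the sample correlation
    over T points is approximately N(rho, sigma_r^2) with
    sigma_r = (1 - rho^2) / sqrt(T - 1).  The expected thresholded
    contribution of one pair is E[r 1(r > c)] = rho (1 - Phi(z)) + sigma_r phi(z)
    with z = (c - rho) / sigma_r, and an in-network voxel has block_size - 1
    within-network pairs (cross-network and background pairs are neglected).
    """
    lam = spec.lambdas[network][(group, condition)]
    block = _block_size(spec.network_blocks[network])
    if lam >= 1.0 and spec.noise_sd == 1.0:
        return float(block - 1)
    rho = lam**2 / (lam**2 + (1.0 - lam**2) * spec.noise_sd**2)
    sigma_r = (1.0 - rho**2) / np.sqrt(spec.t_points - 1)
    z = (threshold - rho) / sigma_r
    pair = rho * sps.norm.sf(z) + sigma_r * sps.norm.pdf(z)
    return float((block - 1) * pair)


# ---------------------------------------------------------------------------
# Long-table level simulation (mixed-model generative process)
# ---------------------------------------------------------------------------

def simulate_long_table(
    n_per_group: int = 8,
    beta: Sequence[float] = (0.0, 0.0, 0.0, 0.0, 0.0),
    participant_sd: float = 0.4,
    resid_sd: float = 0.4,
    mfd_means: Mapping[str, float] | None = None,
    mfd_sds: Mapping[str, float] | None = None,
    network: str = "sensorimotor",
    missing: Sequence[tuple[str, str]] = (),
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate one network's long table directly from the mixed model.

    ``beta`` is (intercept, group, drug, group:drug, mfd) with reference
    levels nonautistic/placebo; each participant gets a Gaussian random
    intercept (sd ``participant_sd``) and each row Gaussian residual noise
    (sd ``resid_sd``).  Used to study the inference machinery at scale
    without generating images.
    """
    if len(beta) != 5:
        raise ValidationError("beta must have 5 entries")
    mfd_means = dict(mfd_means or DEFAULT_MFD_MEANS)
    mfd_sds = dict(mfd_sds or DEFAULT_MFD_SDS)
    rng = np.random.default_rng(seed)
    missing = set((str(p), str(c)) for p, c in missing)
    rows = []
    for group, prefix, g_code in (("nonautistic", "N", 0.0), ("autistic", "A", 1.0)):
        for i in range(n_per_group):
            pid = f"{prefix}{i + 1:02d}"
            b_i = rng.normal(0.0, participant_sd)
            for condition, d_code in (("placebo", 0.0), ("drug", 1.0)):
                mfd = max(0.02, rng.normal(mfd_means[group], mfd_sds[group]))
                y = (
                    beta[0]
                    + beta[1] * g_code
                    + beta[2] * d_code
                    + beta[3] * g_code * d_code
                    + beta[4] * mfd
                    + b_i
                    + rng.normal(0.0, resid_sd)
                )
                if (pid, condition) in missing:
                    continue
                rows.append(
                    {
                        "participant_id": pid,
                        "group": group,
                        "drug": condition,
                        "network": network,
                        "mfd": mfd,
                        "mean_wdc": y,
                    }
                )
    if not rows:
        raise DegenerateInputError("all sessions marked missing")
    return pd.DataFrame(rows)
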