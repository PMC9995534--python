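"""Mass-univariate brain-behavior models with TFCE and permutation FWE.

Each voxel of a cohort's stacked metric maps is regressed on the behavioral
symmetry scores with nuisance covariates (age group, sex, optionally total
intracranial volume).  Two model families are supported:

* **Q1 (shared association)** — one slope per symmetry score common to both
  groups; the contrast isolates one score's slope.
* **Q2 (group interaction)** — group-specific slopes for each score plus
  group/sex main effects; the contrast is the difference of the two group
  slopes for the tested score.

Inference is by threshold-free cluster enhancement of the voxelwise t map
and a Freedman–Lane permutation scheme: the response is residualised
against the nuisance regressors, residual rows are permuted, the full model
is refitted and the image-wide maximum |TFCE| recorded; the FWE-corrected
p-value at a voxel is ``(1 + #{perm max ≥ observed}) / (n_perm + 1)``, with
the unpermuted data contributing the leading 1 so p can never fall below
``1/(n_perm+1)``.  Supra-threshold voxels are grouped into connected
clusters and reported with extent ``K_E``, the minimum-p peak in world
(scanner/MNI) coordinates, and percentage overlap with atlas labels.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from gaitbrain.tfce import TFCEParams, tfce_enhance

__all__ = [
    "ClusterTable",
    "CohortStack",
    "DesignMatrix",
    "GLMResult",
    "VoxelwiseLinearModel",
    "VoxelwiseResults",
    "build_design",
    "extract_clusters",
    "fit_glm",
    "label_clusters",
    "permutation_fwe",
]

logger = logging.getLogger(__name__)


@dataclass
class CohortStack:
    """A cohort's stacked 3D metric maps sharing one grid and mask."""

    data: np.ndarray  # (n_subjects, nx, ny, nz)
    mask: np.ndarray  # boolean, (nx, ny, nz)
    affine: np.ndarray  # 4x4 voxel-to-world
    metric: str = "metric"
    subjects: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 4:
            raise ValueError("stack data must be (subjects, x, y, z)")
        if self.data.shape[1:] != self.mask.shape:
            raise ValueError("mask shape must match the map grid")
        if not np.isfinite(self.data[:, self.mask]).all():
            raise ValueError("non-finite values inside the analysis mask")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def masked_matrix(self) -> np.ndarray:
        """(n_subjects, n_voxels) view of in-mask values."""
        return self.data[:, self.mask]

    def unmask(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter a per-voxel vector back into a 3D volume."""
        vol = np.full(self.mask.shape, fill, dtype=float)
        vol[self.mask] = values
        return vol

    @classmethod
    def from_niftis(cls, paths, mask_path, metric: str = "metric", subjects=None) -> "CohortStack":
        mask_img = nib.load(str(mask_path))
        mask = np.asarray(mask_img.dataobj) > 0.5
        data = np.stack([np.asarray(nib.load(str(p)).dataobj, dtype=float) for p in paths])
        return cls(data=data, mask=mask, affine=mask_img.affine, metric=metric, subjects=subjects)


@dataclass
class DesignMatrix:
    """Subjects × regressors design with named contrast vectors."""

    matrix: pd.DataFrame
    contrasts: dict[str, np.ndarray]
    question: str = "q1"

    @property
    def values(self) -> np.ndarray:
        return self.matrix.to_numpy(dtype=float)

    @property
    def names(self) -> list[str]:
        return list(self.matrix.columns)


def _collinear_columns(X: pd.DataFrame) -> list[str]:
    """Columns involved in rank deficiency (smallest right-singular vector)."""
    A = X.to_numpy(dtype=float)
    _, s, vt = np.linalg.svd(A, full_matrices=False)
    tol = s.max() * max(A.shape) * np.finfo(float).eps
    bad: set[str] = set()
    for i, sv in enumerate(s):
        if sv <= tol:
            involved = np.abs(vt[i]) > 1e-8
            bad.update(np.array(X.columns)[involved])
    return sorted(bad)


def build_design(
    scores: pd.DataFrame,
    score_cols: list[str] | None = None,
    question: str = "q1",
    include_tiv: bool = False,
) -> DesignMatrix:
    """Build the Q1 or Q2 design from a per-subject score/covariate table.

    Parameters
    ----------
    scores:
        One row per subject with the symmetry-score columns plus ``group``
        (young/old) and ``sex`` (F/M), and ``tiv`` when requested.
    score_cols:
        Behavioral regressors to include; defaults to every ``sym_*``
        column.  All listed scores enter the model jointly and one contrast
        per score is produced.
    question:
        ``"q1"`` — shared slopes across groups, contrast = one score's
        slope; ``"q2"`` — group-specific slopes plus main effects, contrast
        = young-minus-old slope difference per score.
    include_tiv:
        Add total intracranial volume (mean-centred) as a nuisance
        covariate, as done for volumetric metrics.
    """
    question = question.lower()
    if question not in ("q1", "q2"):
        raise ValueError("question must be 'q1' or 'q2'")
    if score_cols is None:
        score_cols = [c for c in scores.columns if c.startswith("sym_")]
    if not score_cols:
        raise ValueError("no behavioral score columns selected")
    n = len(scores)
    cols: dict[str, np.ndarray] = {"intercept": np.ones(n)}
    group = (scores["group"].to_numpy() == "old").astype(float)
    contrasts: dict[str, np.ndarray] = {}
    if question == "q1":
        for c in score_cols:
            cols[c] = scores[c].to_numpy(dtype=float)
    else:
        for c in score_cols:
            vals = scores[c].to_numpy(dtype=float)
            cols[f"{c}:young"] = vals * (1.0 - group)
            cols[f"{c}:old"] = vals * group
    cols["group_old"] = group
    cols["sex_male"] = (scores["sex"].to_numpy() == "M").astype(float)
    if include_tiv:
        tiv = scores["tiv"].to_numpy(dtype=float)
        cols["tiv"] = tiv - tiv.mean()
    X = pd.DataFrame(cols)
    if np.linalg.matrix_rank(X.to_numpy(dtype=float)) < X.shape[1]:
        bad = _collinear_columns(X)
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    names = list(X.columns)
    for c in score_cols:
        vec = np.zeros(len(names))
        if question == "q1":
            vec[names.index(c)] = 1.0
        else:
            vec[names.index(f"{c}:young")] = 1.0
            vec[names.index(f"{c}:old")] = -1.0
        contrasts[c] = vec
    return DesignMatrix(matrix=X, contrasts=contrasts, question=question)


@dataclass
class GLMResult:
    """Voxelwise OLS output for one contrast."""

    t: np.ndarray  # (n_voxels,)
    beta: np.ndarray  # (n_regressors, n_voxels)
    df: int
    n_zero_variance: int = 0


def _glm_t(Y: np.ndarray, X: np.ndarray, c: np.ndarray, pinvX: np.ndarray, cXXc: float) -> tuple[np.ndarray, np.ndarray, int]:
    """t statistics for contrast ``c`` at every voxel (column of Y)."""
    beta = pinvX @ Y
    resid = Y - X @ beta
    df = Y.shape[0] - np.linalg.matrix_rank(X)
    rss = (resid**2).sum(axis=0)
    # zero residual variance up to floating point (perfectly fitted voxels)
    zero = rss <= (Y**2).sum(axis=0) * 1e-24
    sigma2 = rss / df
    denom = np.sqrt(sigma2 * cXXc)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(zero | (denom == 0), 0.0, (c @ beta) / denom)
    return t, beta, int((zero | (denom == 0)).sum())


def fit_glm(stack: CohortStack, design: DesignMatrix, contrast) -> GLMResult:
    """Ordinary least squares per voxel with a t contrast.

    ``contrast`` may be a contrast name from the design or an explicit
    weight vector.  Voxels with zero residual variance get t = 0 (their
    count is logged and reported in the result).
    """
    c = design.contrasts[contrast] if isinstance(contrast, str) else np.asarray(contrast, float)
    X = design.values
    if stack.n_subjects != X.shape[0]:
        raise ValueError("stack and design have different numbers of subjects")
    if stack.n_subjects <= X.shape[1]:
        raise ValueError("need more subjects than regressors")
    Y = stack.masked_matrix()
    pinvX = np.linalg.pinv(X)
    cXXc = float(c @ np.linalg.pinv(X.T @ X) @ c)
    t, beta, n_zero = _glm_t(Y, X, c, pinvX, cXXc)
    if n_zero:
        logger.info("fit_glm: %d voxels with zero residual variance (t set to 0)", n_zero)
    df = Y.shape[0] - np.linalg.matrix_rank(X)
    return GLMResult(t=t, beta=beta, df=df, n_zero_variance=n_zero)


def _permutation_indices(rng: np.random.Generator, n: int, n_perm: int):
    """Row permutations for the null ensemble, reproducible from the seed.

    If ``n_perm`` is not below the number of distinguishable permutations
    (n!), warns and enumerates all of them exactly (identity excluded — it
    is accounted for by the +1 of the p-value formula).
    """
    n_distinct = math.factorial(n)
    if n_perm >= n_distinct:
        warnings.warn(
            f"n_perm={n_perm} >= {n_distinct} distinguishable permutations; "
            "enumerating all permutations exactly",
            stacklevel=3,
        )
        perms = [np.array(p) for p in itertools.permutations(range(n))]
        return perms[1:]  # drop identity: it is the observed member
    return [rng.permutation(n) for _ in range(n_perm)]


def permutation_fwe(
    stack: CohortStack,
    design: DesignMatrix,
    contrast,
    n_perm: int = 5000,
    seed: int = 0,
    tfce_params: TFCEParams | None = None,
    two_sided: bool = True,
) -> dict:
    """FWE-corrected voxelwise p-values via Freedman–Lane max-TFCE permutation.

    The response is residualised against the nuisance regressors (design
    columns with zero contrast weight), residual rows are permuted and added
    back to the nuisance fit, the full model is refitted and the TFCE map's
    image-wide maximum absolute value recorded.  Corrected
    ``p(v) = (1 + #{perm max ≥ |TFCE_obs(v)|}) / (n_perm + 1)``.

    Returns a dict with the observed ``t`` map, ``tfce`` map, per-voxel
    ``p`` values, the null ``max_tfce`` distribution, and the GLM result.
    """
    tfce_params = tfce_params or TFCEParams()
    c = design.contrasts[contrast] if isinstance(contrast, str) else np.asarray(contrast, float)
    X = design.values
    n = X.shape[0]
    Y = stack.masked_matrix()
    pinvX = np.linalg.pinv(X)
    cXXc = float(c @ np.linalg.pinv(X.T @ X) @ c)

    obs = fit_glm(stack, design, c)
    t_vol = stack.unmask(obs.t)
    tfce_obs = tfce_enhance(t_vol, tfce_params, mask=stack.mask, two_sided=two_sided)
    obs_vals = np.abs(tfce_obs[stack.mask])

    nuisance = np.abs(c) == 0
    Z = X[:, nuisance]
    if Z.shape[1]:
        fit_z = Z @ (np.linalg.pinv(Z) @ Y)
    else:
        fit_z = np.zeros_like(Y)
    resid = Y - fit_z

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    perms = _permutation_indices(rng, n, n_perm)
    max_null = np.empty(len(perms))
    for j, perm in enumerate(perms):
        Yp = fit_z + resid[perm]
        t_p, _, _ = _glm_t(Yp, X, c, pinvX, cXXc)
        enh = tfce_enhance(stack.unmask(t_p), tfce_params, mask=stack.mask, two_sided=two_sided)
        max_null[j] = np.abs(enh).max()
    exceed = (max_null[None, :] >= obs_vals[:, None]).sum(axis=1)
    p = (1.0 + exceed) / (len(perms) + 1.0)
    return {
        "t": t_vol,
        "tfce": tfce_obs,
        "p": p,
        "p_vol": stack.unmask(p, fill=1.0),
        "max_null": max_null,
        "glm": obs,
        "n_perm": len(perms),
    }


def _structure(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(3, {6: 1, 18: 2, 26: 3}[connectivity])


@dataclass
class ClusterTable:
    """Supra-threshold clusters with extents, peaks and corrected p-values.

    ``table`` columns: ``cluster, k_e, p_fwe, i, j, k, x, y, z`` (peak
    lattice index and world coordinate).  ``cluster_map`` labels each voxel
    with its cluster id (0 = background).
    """

    table: pd.DataFrame
    cluster_map: np.ndarray
    affine: np.ndarray
    alpha: float = 0.05
    labels: pd.DataFrame | None = None

    def __len__(self) -> int:
        return len(self.table)

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        if self.labels is not None and len(self.labels):
            merged = (
                self.labels.groupby("cluster")
                .apply(
                    lambda g: "; ".join(
                        f"{r.label_name} ({r.overlap_pct:.0f}%)" for r in g.itertuples()
                    ),
                    include_groups=False,
                )
                .rename("labels")
            )
            out = out.merge(merged, on="cluster", how="left")
        out.to_csv(path, sep="\t", index=False)


def extract_clusters(
    p_vol: np.ndarray,
    mask: np.ndarray,
    affine: np.ndarray,
    alpha: float = 0.05,
    connectivity: int = 26,
    stat_vol: np.ndarray | None = None,
) -> ClusterTable:
    """Connected components of {p < alpha} inside the mask.

    The peak of each cluster is its minimum-p voxel (ties broken by array
    order; ``stat_vol``, when given, breaks remaining ties by largest
    statistic).  World coordinates come from the affine.
    """
    sig = (p_vol < alpha) & mask
    lab, n_clusters = ndimage.label(sig, structure=_structure(connectivity))
    rows = []
    for cid in range(1, n_clusters + 1):
        where = np.argwhere(lab == cid)
        pvals = p_vol[tuple(where.T)]
        best = np.flatnonzero(pvals == pvals.min())
        if stat_vol is not None and best.size > 1:
            stats = stat_vol[tuple(where[best].T)]
            best = best[np.argmax(np.abs(stats))]
        else:
            best = best[0]
        peak = where[best]
        world = affine @ np.append(peak, 1.0)
        rows.append(
            {
                "cluster": cid,
                "k_e": int(len(where)),
                "p_fwe": float(pvals.min()),
                "i": int(peak[0]),
                "j": int(peak[1]),
                "k": int(peak[2]),
                "x": float(world[0]),
                "y": float(world[1]),
                "z": float(world[2]),
            }
        )
    table = pd.DataFrame(
        rows, columns=["cluster", "k_e", "p_fwe", "i", "j", "k", "x", "y", "z"]
    )
    if len(table):
        table = table.sort_values("k_e", ascending=False, ignore_index=True)
    return ClusterTable(table=table, cluster_map=lab, affine=affine, alpha=alpha)


def _resample_nearest(atlas: np.ndarray, atlas_affine: np.ndarray, shape, affine) -> np.ndarray:
    """Nearest-neighbour resampling of a label volume onto a target grid."""
    inv = np.linalg.inv(atlas_affine) @ affine
    idx = np.indices(shape).reshape(3, -1)
    src = inv[:3, :3] @ idx + inv[:3, 3:4]
    src = np.round(src).astype(int)
    ok = np.all((src >= 0) & (src < np.array(atlas.shape)[:, None]), axis=0)
    out = np.zeros(np.prod(shape), dtype=atlas.dtype)
    out[ok] = atlas[tuple(src[:, ok])]
    return out.reshape(shape)


def label_clusters(
    clusters: ClusterTable,
    atlas: np.ndarray,
    lookup: pd.DataFrame,
    atlas_affine: np.ndarray | None = None,
    min_overlap_pct: float = 5.0,
) -> ClusterTable:
    """Attach atlas-label overlap percentages to each cluster.

    For every cluster, the percentage of its voxels falling in each atlas
    label is computed; labels below ``min_overlap_pct`` (default 5%) are
    suppressed.  The atlas must share the cluster grid, or be accompanied
    by an affine for nearest-neighbour resampling onto it.
    """
    atlas = np.asarray(atlas)
    if atlas.shape != clusters.cluster_map.shape:
        if atlas_affine is None:
            raise ValueError("atlas grid differs from the cluster grid and no affine was given")
        atlas = _resample_nearest(atlas, atlas_affine, clusters.cluster_map.shape, clusters.affine)
    names = dict(zip(lookup["label_id"], lookup["label_name"]))
    rows = []
    for cid in clusters.table["cluster"]:
        in_cluster = clusters.cluster_map == cid
        total = int(in_cluster.sum())
        ids, counts = np.unique(atlas[in_cluster], return_counts=True)
        for lid, cnt in zip(ids, counts):
            if lid == 0:
                continue
            pct = 100.0 * cnt / total
            if pct >= min_overlap_pct:
                rows.append(
                    {
                        "cluster": int(cid),
                        "label_id": int(lid),
                        "label_name": names.get(int(lid), f"label {lid}"),
                        "overlap_pct": pct,
                    }
                )
    labels = pd.DataFrame(rows, columns=["cluster", "label_id", "label_name", "overlap_pct"])
    return ClusterTable(
        table=clusters.table,
        cluster_map=clusters.cluster_map,
        affine=clusters.affine,
        alpha=clusters.alpha,
        labels=labels,
    )


# ---------------------------------------------------------------------------
# Model / Results


class VoxelwiseLinearModel:
    """Mass-univariate linear model of brain maps on behavioral scores.

    Parameters
    ----------
    stack:
        :class:`CohortStack` of subject maps (the dependent variable).
    design:
        :class:`DesignMatrix`, typically from :func:`build_design`.

    Use :meth:`from_dataframe` to build design and model in one step from a
    per-subject score/covariate table.
    """

    def __init__(self, stack: CohortStack, design: DesignMatrix) -> None:
        if stack.n_subjects != design.matrix.shape[0]:
            raise ValueError("stack and design have different numbers of subjects")
        self.stack = stack
        self.design = design

    @classmethod
    def from_dataframe(
        cls,
        stack: CohortStack,
        table: pd.DataFrame,
        score_cols: list[str] | None = None,
        question: str = "q1",
        include_tiv: bool = False,
    ) -> "VoxelwiseLinearModel":
        return cls(stack, build_design(table, score_cols, question, include_tiv))

    def fit(
        self,
        contrast: str | np.ndarray | None = None,
        n_perm: int = 5000,
        seed: int = 0,
        tfce_params: TFCEParams | None = None,
        alpha: float = 0.05,
        connectivity: int | None = None,
    ) -> "VoxelwiseResults":
        """Fit the GLM and run TFCE permutation inference for one contrast.

        ``contrast`` defaults to the design's first contrast.  Returns a
        :class:`VoxelwiseResults`.
        """
        if contrast is None:
            contrast = next(iter(self.design.contrasts))
        tfce_params = tfce_params or TFCEParams()
        if connectivity is None:
            connectivity = tfce_params.connectivity
        out = permutation_fwe(
            self.stack, self.design, contrast, n_perm=n_perm, seed=seed, tfce_params=tfce_params
        )
        return VoxelwiseResults(
            model=self,
            contrast=contrast if isinstance(contrast, str) else "custom",
            t_vol=out["t"],
            tfce_vol=out["tfce"],
            p_vol=out["p_vol"],
            max_null=out["max_null"],
            glm=out["glm"],
            n_perm=out["n_perm"],
            alpha=alpha,
            connectivity=connectivity,
            tfce_params=tfce_params,
            seed=seed,
        )


@dataclass
class VoxelwiseResults:
    """Fitted voxelwise model for one contrast: maps, null distribution,
    cluster extraction, atlas labeling and reporting."""

    model: VoxelwiseLinearModel = field(repr=False)
    contrast: str
    t_vol: np.ndarray = field(repr=False)
    tfce_vol: np.ndarray = field(repr=False)
    p_vol: np.ndarray = field(repr=False)
    max_null: np.ndarray = field(repr=False)
    glm: GLMResult = field(repr=False)
    n_perm: int = 0
    alpha: float = 0.05
    connectivity: int = 26
    tfce_params: TFCEParams | None = None
    seed: int = 0

    def clusters(self, alpha: float | None = None) -> ClusterTable:
        return extract_clusters(
            self.p_vol,
            self.model.stack.mask,
            self.model.stack.affine,
            alpha=self.alpha if alpha is None else alpha,
            connectivity=self.connectivity,
            stat_vol=self.tfce_vol,
        )

    def label_clusters(
        self, atlas, lookup, atlas_affine=None, min_overlap_pct: float = 5.0, alpha=None
    ) -> ClusterTable:
        return label_clusters(self.clusters(alpha), atlas, lookup, atlas_affine, min_overlap_pct)

    def summary(self) -> str:
        stack = self.model.stack
        design = self.model.design
        lines = [
            f"Voxelwise linear model — metric {stack.metric!r}, "
            f"question {design.question.upper()}, contrast {self.contrast!r}",
            f"subjects: {stack.n_subjects}   voxels: {stack.n_voxels}   df: {self.glm.df}",
            f"regressors: {', '.join(design.names)}",
            f"permutations: {self.n_perm} (Freedman–Lane, max-|TFCE| FWE)   "
            f"seed: {self.seed}",
            f"min corrected p: {self.p_vol[stack.mask].min():.4f}   alpha: {self.alpha}",
        ]
        ct = self.clusters()
        if len(ct):
            lines.append(f"significant clusters (p < {self.alpha}):")
            lines.append(ct.table.to_string(index=False))
        else:
            lines.append("no significant clusters")
        return "\n".join(lines)

    def save(self, outdir) -> dict:
        """Write t/TFCE/p maps as NIfTI-1; returns the path map."""
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        aff = self.model.stack.affine
        for name, vol in (("t", self.t_vol), ("tfce", self.tfce_vol), ("p_fwe", self.p_vol)):
            path = outdir / f"{self.model.stack.metric}_{self.contrast}_{name}.nii"
            nib.save(nib.Nifti1Image(vol.astype(np.float64), aff), path)
            paths[name] = path
        return paths

    def plot_slices(self, what: str = "t", n_slices: int = 6, axes=None):
        """Axial montage of a result map, masked."""
        import matplotlib.pyplot as plt

        vol = {"t": self.t_vol, "tfce": self.tfce_vol, "p": self.p_vol}[what]
        mask = self.model.stack.mask
        shown = np.where(mask, vol, np.nan)
        zs = np.linspace(0, vol.shape[2] - 1, n_slices).astype(int)
        if axes is None:
            _, axes = plt.subplots(1, n_slices, figsize=(2 * n_slices, 2.4))
        vmax = np.nanmax(np.abs(shown)) or 1.0
        for ax, z in zip(np.atleast_1d(axes), zs):
            ax.imshow(shown[:, :, z].T, origin="lower", cmap="coolwarm", vmin=-vmax, vmax=vmax)
            ax.set_title(f"z={z}", fontsize=8)
            ax.axis("off")
        return axes
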