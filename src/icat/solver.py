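"""Global alignment solver: one sparse linear least-squares system over
per-tile transforms, driven by weighted point correspondences.

Given tiles with stage-derived (or previously solved) initial transforms
``T_init`` and point-match sets between tile pairs, the solver minimizes

    Σ_matches Σ_i w_i ‖T_a p_i − T_b q_i‖²  +  λ Σ_tiles ‖T − T_init‖²_F

with one tile anchored to its initial transform (gauge fixing). Three
transform models are supported: ``translation`` (2 unknowns per tile, linear
part frozen at T_init), ``rigid`` (linearized similarity, 4 unknowns), and
``affine`` (6 unknowns). All models are linear in their unknowns, so the
optimum is the solution of one sparse normal-equations system.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import sparse
from scipy.sparse import linalg as spla

from .errors import ConnectivityError, SolverError
from .tiles import PointMatchSet, Tile
from .transforms import AffineTransform2D

__all__ = ["SolverOptions", "SolveResult", "solve_tile_transforms"]

_MODEL_DOF = {"translation": 2, "rigid": 4, "affine": 6}


@dataclass
class SolverOptions:
    """Tunables of the global alignment solve.

    ``lam`` is the regularization weight pulling each tile toward its
    stage-derived initial transform, per match-point-equivalent; ``model``
    selects the per-tile transform parameterization; ``anchor_tile`` fixes
    the gauge (default: lexicographically smallest tile id). ``max_iter`` /
    ``tol`` switch the solve to iterative LSMR for very large systems.
    """

    lam: float = 0.005
    model: str = "translation"
    anchor_tile: str | None = None
    max_iter: int | None = None
    tol: float = 1e-12

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.model not in _MODEL_DOF:
            raise ValueError(f"unknown model {self.model!r}")


@dataclass
class SolveResult:
    transforms: dict[str, AffineTransform2D]
    residuals: dict[tuple[str, str], float] = field(default_factory=dict)
    rms: float = 0.0


def _params_from_transform(
    t: AffineTransform2D, model: str, center: np.ndarray
) -> np.ndarray:
    """Model parameters with the translation expressed as the world position
    of the tile center. Centering keeps the design matrix well conditioned
    (raw pixel coordinates run into the hundreds; their normal equations
    would square that) and makes the regularizer penalize center drift
    rather than the origin's."""
    u = t.linear @ center + t.translation
    if model == "translation":
        return u
    if model == "rigid":
        a = 0.5 * (t.a11 + t.a22)
        b = 0.5 * (t.a21 - t.a12)
        return np.array([a, b, u[0], u[1]])
    return np.array([t.a11, t.a12, u[0], t.a21, t.a22, u[1]])


def _transform_from_params(
    params: np.ndarray, init: AffineTransform2D, model: str, center: np.ndarray
) -> AffineTransform2D:
    if model == "translation":
        lin = init.linear
        t = params - lin @ center
        return AffineTransform2D(
            init.a11, init.a12, init.a21, init.a22, t[0], t[1]
        )
    if model == "rigid":
        a, b = params[0], params[1]
        lin = np.array([[a, -b], [b, a]])
        t = params[2:] - lin @ center
        return AffineTransform2D(a, -b, b, a, t[0], t[1])
    lin = np.array([[params[0], params[1]], [params[3], params[4]]])
    t = np.array([params[2], params[5]]) - lin @ center
    return AffineTransform2D(
        params[0], params[1], params[3], params[4], t[0], t[1]
    )


def _point_rows(
    points: np.ndarray, model: str, init: AffineTransform2D, center: np.ndarray
):
    """Coefficient rows (x-row, y-row) of world coordinates w.r.t. the tile's
    center-relative unknowns, plus a constant world offset from frozen
    parts: world(p) = A (p − c) + u."""
    n = len(points)
    rel = points - center
    if model == "translation":
        rows_x = np.zeros((n, 2))
        rows_y = np.zeros((n, 2))
        rows_x[:, 0] = 1.0
        rows_y[:, 1] = 1.0
        const = rel @ init.linear.T  # frozen linear part
        return rows_x, rows_y, const
    if model == "rigid":
        rows_x = np.zeros((n, 4))
        rows_y = np.zeros((n, 4))
        rows_x[:, 0] = rel[:, 0]
        rows_x[:, 1] = -rel[:, 1]
        rows_x[:, 2] = 1.0
        rows_y[:, 0] = rel[:, 1]
        rows_y[:, 1] = rel[:, 0]
        rows_y[:, 3] = 1.0
        return rows_x, rows_y, np.zeros((n, 2))
    rows_x = np.zeros((n, 6))
    rows_y = np.zeros((n, 6))
    rows_x[:, 0] = rel[:, 0]
    rows_x[:, 1] = rel[:, 1]
    rows_x[:, 2] = 1.0
    rows_y[:, 3] = rel[:, 0]
    rows_y[:, 4] = rel[:, 1]
    rows_y[:, 5] = 1.0
    return rows_x, rows_y, np.zeros((n, 2))


def solve_tile_transforms(
    tiles: dict[str, Tile] | list[Tile],
    matches: list[PointMatchSet],
    init: dict[str, AffineTransform2D],
    opts: SolverOptions | None = None,
) -> SolveResult:
    """Solve the global alignment system for all tiles at once.

    Raises :class:`ConnectivityError` (listing components) if the match graph
    is disconnected, and :class:`SolverError` if the system is rank deficient
    (e.g. λ = 0 with too few constraints for the chosen model).
    """
    opts = opts or SolverOptions()
    if not isinstance(tiles, dict):
        tiles = {t.tile_id: t for t in tiles}
    ids = sorted(tiles)
    if not ids:
        raise SolverError("no tiles to solve")
    for m in matches:
        if m.tile_id_a not in tiles or m.tile_id_b not in tiles:
            raise ValueError(f"match references unknown tile {m.tile_id_a}/{m.tile_id_b}")
    for tid in ids:
        if tid not in init:
            raise ValueError(f"no initial transform for tile {tid}")

    graph = nx.Graph()
    graph.add_nodes_from(ids)
    graph.add_edges_from(
        (m.tile_id_a, m.tile_id_b) for m in matches if len(m) > 0
    )
    components = [sorted(c) for c in nx.connected_components(graph)]
    if len(components) > 1:
        raise ConnectivityError(
            f"match graph has {len(components)} components: "
            + "; ".join("{" + ", ".join(c) + "}" for c in components),
            components=components,
        )

    anchor = opts.anchor_tile if opts.anchor_tile is not None else ids[0]
    if anchor not in tiles:
        raise ValueError(f"anchor tile {anchor!r} not among tiles")
    dof = _MODEL_DOF[opts.model]
    free_ids = [tid for tid in ids if tid != anchor]
    col_of = {tid: i * dof for i, tid in enumerate(free_ids)}
    n_unknowns = dof * len(free_ids)
    centers = {
        tid: np.array([(t.width - 1) / 2.0, (t.height - 1) / 2.0])
        for tid, t in tiles.items()
    }
    anchor_params = _params_from_transform(
        init[anchor], opts.model, centers[anchor]
    )

    rows_i: list[np.ndarray] = []
    cols_i: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    rhs_chunks: list[np.ndarray] = []
    row_counter = 0

    def _emit(rows, cols, values):
        nonlocal row_counter
        rows_i.append(rows + row_counter)
        cols_i.append(cols)
        vals.append(values)

    for m in matches:
        if len(m) == 0:
            continue
        sw = np.sqrt(m.weights)
        rhs_pair = np.zeros((len(m), 2))
        for side, pts, sign in (
            (m.tile_id_a, m.points_a, +1.0),
            (m.tile_id_b, m.points_b, -1.0),
        ):
            rx, ry, const = _point_rows(pts, opts.model, init[side], centers[side])
            rhs_pair -= sign * const
            if side == anchor:
                world = np.column_stack([rx @ anchor_params, ry @ anchor_params])
                rhs_pair -= sign * world
                continue
            base = col_of[side]
            n = len(pts)
            for coord, r in ((0, rx), (1, ry)):
                nz = np.nonzero(r)
                _emit(
                    2 * nz[0] + coord,
                    base + nz[1],
                    sign * r[nz] * sw[nz[0]],
                )
        rhs_chunks.append((rhs_pair * sw[:, None]).ravel())
        row_counter += 2 * len(m)

    if opts.lam > 0:
        sl = np.sqrt(opts.lam)
        for tid in free_ids:
            p0 = _params_from_transform(init[tid], opts.model, centers[tid])
            base = col_of[tid]
            _emit(np.arange(dof), base + np.arange(dof), np.full(dof, sl))
            rhs_chunks.append(sl * p0)
            row_counter += dof

    if n_unknowns == 0:
        transforms = {anchor: init[anchor]}
    else:
        if row_counter == 0:
            raise SolverError("no constraints: empty matches with lam=0")
        design = sparse.coo_matrix(
            (
                np.concatenate(vals),
                (np.concatenate(rows_i), np.concatenate(cols_i)),
            ),
            shape=(row_counter, n_unknowns),
        ).tocsr()
        rhs = np.concatenate(rhs_chunks)
        normal = (design.T @ design).tocsc()
        atb = design.T @ rhs
        if opts.max_iter is not None:
            sol = spla.lsmr(
                design, rhs, atol=opts.tol, btol=opts.tol, maxiter=opts.max_iter
            )[0]
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("error", spla.MatrixRankWarning)
                try:
                    sol = spla.spsolve(normal, atb)
                except (spla.MatrixRankWarning, RuntimeError) as exc:
                    raise SolverError(
                        f"rank-deficient alignment system ({exc}); "
                        "add matches or set lam > 0"
                    ) from exc
        if not np.all(np.isfinite(sol)):
            raise SolverError("rank-deficient alignment system (non-finite solution)")
        transforms = {anchor: init[anchor]}
        for tid in free_ids:
            base = col_of[tid]
            transforms[tid] = _transform_from_params(
                sol[base : base + dof], init[tid], opts.model, centers[tid]
            )

    residuals: dict[tuple[str, str], float] = {}
    sq_sum, n_pts = 0.0, 0
    for m in matches:
        if len(m) == 0:
            continue
        wa = transforms[m.tile_id_a].apply(m.points_a)
        wb = transforms[m.tile_id_b].apply(m.points_b)
        d2 = np.sum((wa - wb) ** 2, axis=1)
        residuals[(m.tile_id_a, m.tile_id_b)] = float(np.sqrt(d2.mean()))
        sq_sum += d2.sum()
        n_pts += len(d2)
    rms = float(np.sqrt(sq_sum / n_pts)) if n_pts else 0.0
    return SolveResult(transforms=transforms, residuals=residuals, rms=rms)
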