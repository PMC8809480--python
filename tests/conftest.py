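"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from icat.tiles import PointMatchSet, Tile
from icat.transforms import AffineTransform2D


def make_tile(
    tile_id: str,
    size: int = 64,
    z: int = 0,
    stage_xy=(0.0, 0.0),
    pixel_size_nm: float = 5.0,
    transform: AffineTransform2D | None = None,
    fill: int = 1,
) -> Tile:
    """Minimal tile whose image content is irrelevant (solver-level tests)."""
    return Tile(
        tile_id=tile_id,
        modality="EM_HIGH",
        section_index=z,
        image=np.full((size, size), fill, dtype=np.uint8),
        stage_xy=stage_xy,
        pixel_size_nm=pixel_size_nm,
        transform=transform or AffineTransform2D.identity(),
    )


def synth_matches(
    tile_a: Tile,
    tile_b: Tile,
    truth_a: AffineTransform2D,
    truth_b: AffineTransform2D,
    n: int = 20,
    noise: float = 0.0,
    rng: np.random.Generator | None = None,
) -> PointMatchSet:
    """Point matches consistent with known truth transforms plus isotropic
    Gaussian noise — the generator-truth route to solver tests."""
    rng = rng or np.random.default_rng(0)
    p = rng.uniform(0, tile_a.width - 1, (n, 2))
    q = truth_b.invert().apply(truth_a.apply(p))
    if noise > 0:
        q = q + rng.normal(0, noise, q.shape)
    return PointMatchSet(tile_a.tile_id, tile_b.tile_id, np.stack([p, q], axis=1), np.ones(n))


def dense_solve(
    tiles: list[Tile],
    matches: list[PointMatchSet],
    init: dict[str, AffineTransform2D],
    lam: float,
    model: str,
    anchor: str | None = None,
) -> dict[str, AffineTransform2D]:
    """Brute-force dense normal-equations oracle for the global alignment
    objective, built point by point with plain numpy.

    Same objective as the sparse solver (center-relative parameterization,
    anchored gauge, λ-weighted pull to the initial transforms), assembled
    independently: one dense design matrix, ``np.linalg.lstsq``.
    """
    ids = sorted(t.tile_id for t in tiles)
    tile_of = {t.tile_id: t for t in tiles}
    anchor = anchor or ids[0]
    dof = {"translation": 2, "rigid": 4, "affine": 6}[model]
    free = [i for i in ids if i != anchor]
    col = {tid: k * dof for k, tid in enumerate(free)}

    def center(tid):
        t = tile_of[tid]
        return np.array([(t.width - 1) / 2.0, (t.height - 1) / 2.0])

    def params(tid):
        t = init[tid]
        c = center(tid)
        u = t.linear @ c + t.translation
        if model == "translation":
            return u
        if model == "rigid":
            return np.array([0.5 * (t.a11 + t.a22), 0.5 * (t.a21 - t.a12), u[0], u[1]])
        return np.array([t.a11, t.a12, u[0], t.a21, t.a22, u[1]])

    def world_coeff(tid, point):
        """(coeff_x, coeff_y, const_x, const_y) of the world position as a
        linear function of the tile's unknowns."""
        c = center(tid)
        r = np.asarray(point, float) - c
        cx = np.zeros(dof)
        cy = np.zeros(dof)
        kx = ky = 0.0
        if model == "translation":
            lin = init[tid].linear
            cx[0] = 1.0
            cy[1] = 1.0
            kx, ky = lin @ r
        elif model == "rigid":
            cx[:] = [r[0], -r[1], 1.0, 0.0]
            cy[:] = [r[1], r[0], 0.0, 1.0]
        else:
            cx[:] = [r[0], r[1], 1.0, 0.0, 0.0, 0.0]
            cy[:] = [0.0, 0.0, 0.0, r[0], r[1], 1.0]
        return cx, cy, kx, ky

    rows = []
    rhs = []
    n_unk = dof * len(free)
    for m in matches:
        for (pa, pb), w in zip(m.pairs, m.weights):
            sw = np.sqrt(w)
            for coord in (0, 1):
                row = np.zeros(n_unk)
                b = 0.0
                for tid, pt, sign in ((m.tile_id_a, pa, 1.0), (m.tile_id_b, pb, -1.0)):
                    cx, cy, kx, ky = world_coeff(tid, pt)
                    coeff = cx if coord == 0 else cy
                    const = kx if coord == 0 else ky
                    b -= sign * const
                    if tid == anchor:
                        b -= sign * float(coeff @ params(tid))
                    else:
                        row[col[tid] : col[tid] + dof] += sign * coeff
                rows.append(sw * row)
                rhs.append(sw * b)
    if lam > 0:
        sl = np.sqrt(lam)
        for tid in free:
            p0 = params(tid)
            for k in range(dof):
                row = np.zeros(n_unk)
                row[col[tid] + k] = sl
                rows.append(row)
                rhs.append(sl * p0[k])

    out = {anchor: init[anchor]}
    if n_unk:
        design = np.array(rows)
        sol = np.linalg.lstsq(design, np.array(rhs), rcond=None)[0]
        for tid in free:
            th = sol[col[tid] : col[tid] + dof]
            c = center(tid)
            if model == "translation":
                lin = init[tid].linear
                t = th - lin @ c
                out[tid] = AffineTransform2D(
                    lin[0, 0], lin[0, 1], lin[1, 0], lin[1, 1], t[0], t[1]
                )
            elif model == "rigid":
                a, b_ = th[0], th[1]
                lin = np.array([[a, -b_], [b_, a]])
                t = th[2:] - lin @ c
                out[tid] = AffineTransform2D(a, -b_, b_, a, t[0], t[1])
            else:
                lin = np.array([[th[0], th[1]], [th[3], th[4]]])
                t = np.array([th[2], th[5]]) - lin @ c
                out[tid] = AffineTransform2D(
                    th[0], th[1], th[3], th[4], t[0], t[1]
                )
    return out


def gauge_removed_position_errors(
    solved: dict[str, AffineTransform2D],
    truth: dict[str, AffineTransform2D],
    tiles: list[Tile],
) -> np.ndarray:
    """Tile-center position errors after removing the global translation
    (the gauge freedom of a relative alignment)."""
    errs = []
    for t in tiles:
        c = np.array([(t.width - 1) / 2.0, (t.height - 1) / 2.0])
        errs.append(solved[t.tile_id].apply(c) - truth[t.tile_id].apply(c))
    errs = np.array(errs)
    return errs - errs.mean(axis=0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
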