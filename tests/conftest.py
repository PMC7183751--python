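import numpy as np
import pytest

import capmap


@pytest.fixture(scope="session")
def small_valley():
    """A compact noise-free U-valley with ground truth, shared read-only."""
    spec = capmap.SyntheticValleySpec(
        length_m=3000, width_m=1500, depth_m=200, floor_width_m=300,
        cell_size_m=30)
    dem, truth = capmap.make_valley_dem(spec)
    return spec, dem, truth


@pytest.fixture(scope="session")
def klipfontein_run():
    """Full model run on the Klipfontein-like calibration valley."""
    dem, truth = capmap.make_valley_dem(capmap.KLIPFONTEIN)
    derivs, mask = capmap.run_cap_model(dem, capmap.KLIPFONTEIN.radius_m)
    return dem, truth, derivs, mask


def random_dem(rng: np.random.Generator, nrows: int = 50, ncols: int = 50,
               cell: float = 30.0) -> capmap.DEMGrid:
    z = rng.uniform(0.0, 500.0, size=(nrows, ncols))
    return capmap.DEMGrid(z, cell)


# ---------------------------------------------------------------------------
# independent brute-force oracles (deliberately naive; never share code with
# the implementation under test)


def rank_oracle(dem: capmap.DEMGrid, radius_m: float) -> np.ndarray:
    """Per-cell window sort: midrank of the cell among valid window cells."""
    from scipy.stats import rankdata

    k = max(1, int(round(radius_m / dem.cell_size_m)))
    min_cells = min(10, (2 * k + 1) ** 2)
    z = dem.elevations
    valid = ~dem.nodata_mask
    nrows, ncols = z.shape
    out = np.full((nrows, ncols), np.nan)
    for i in range(nrows):
        for j in range(ncols):
            if not valid[i, j]:
                continue
            win = z[max(0, i - k): i + k + 1, max(0, j - k): j + k + 1]
            wv = win[np.isfinite(win)]
            if len(wv) < min_cells:
                continue
            ranks = rankdata(wv, method="average")
            self_rank = ranks[np.argwhere(wv == z[i, j])[0][0]]
            out[i, j] = min(max((self_rank - 1.0) / (len(wv) - 1.0), 0.0), 1.0)
    return out


def curvature_oracle(dem: capmap.DEMGrid, radius_m: float) -> np.ndarray:
    """Direct per-cell evaluation of the eight-direction formula."""
    k = max(1, int(round(radius_m / dem.cell_size_m)))
    r = k * dem.cell_size_m
    z = dem.elevations
    nrows, ncols = z.shape
    out = np.full((nrows, ncols), np.nan)
    offsets = {"w": (0, -k), "e": (0, k), "n": (-k, 0), "s": (k, 0),
               "nw": (-k, -k), "se": (k, k), "ne": (-k, k), "sw": (k, -k)}
    for i in range(nrows):
        for j in range(ncols):
            s = {}
            ok = np.isfinite(z[i, j])
            for name, (di, dj) in offsets.items():
                ii, jj = i + di, j + dj
                if 0 <= ii < nrows and 0 <= jj < ncols and \
                        np.isfinite(z[ii, jj]):
                    s[name] = z[ii, jj]
                else:
                    ok = False
            if not ok:
                continue
            zc = z[i, j]
            out[i, j] = 0.25 * (
                ((zc - (s["w"] + s["e"]) / 2.0)
                 + (zc - (s["n"] + s["s"]) / 2.0)) / (2.0 * r)
                + ((zc - (s["sw"] + s["ne"]) / 2.0)
                   + (zc - (s["nw"] + s["se"]) / 2.0))
                / (2.0 * np.sqrt(2.0) * r))
    return out


def agreement_oracle(pred: np.ndarray, ref: np.ndarray):
    """Brute-force recall / false-positive fraction / boundary offset."""
    pred = pred.astype(bool)
    ref = ref.astype(bool)
    recall = (pred & ref).sum() / ref.sum()
    fp = (pred & ~ref).sum() / pred.sum() if pred.sum() else 0.0

    def boundary_cells(mask):
        cells = []
        nrows, ncols = mask.shape
        for i in range(nrows):
            for j in range(ncols):
                if not mask[i, j]:
                    continue
                for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    ii, jj = i + di, j + dj
                    if not (0 <= ii < nrows and 0 <= jj < ncols) \
                            or not mask[ii, jj]:
                        cells.append((i, j))
                        break
        return np.array(cells, dtype=float)

    pb, rb = boundary_cells(pred), boundary_cells(ref)
    if len(pb) and len(rb):
        from scipy.spatial.distance import cdist
        d = cdist(pb, rb)
        offset = 0.5 * (d.min(axis=1).mean() + d.min(axis=0).mean())
    else:
        offset = float("nan")
    return float(recall), float(fp), float(offset)
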