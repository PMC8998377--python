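import numpy as np
import pytest

from landrisk import synthetic_data as sd
from landrisk.grid_io import LandUseGrid


def make_grid(values, cell_size=30.0, mask=None, class_table=None, epoch="test"):
    values = np.asarray(values)
    if class_table is None:
        codes = np.unique(values)
        class_table = {int(c): {"name": f"class{c}", "vulnerability_level": 3} for c in codes}
    return LandUseGrid(values=values, cell_size=cell_size, nodata_mask=mask, class_table=class_table, epoch_label=epoch)


@pytest.fixture(scope="session")
def cma_mini():
    """The default 200x200 synthetic landscape with drivers (one build per run)."""
    grid, drivers = sd.generate_landscape(sd.cma_mini_spec(seed=11))
    return grid, drivers


@pytest.fixture(scope="session")
def cma_mini_pair(cma_mini):
    """Two-epoch synthetic pair with programmed, driver-dependent change."""
    grid, drivers = cma_mini
    rules = sd.default_change_rules(grid.n_unmasked)
    epoch2, changed, truth = sd.generate_change(grid, drivers, rules, seed=12)
    return grid, epoch2, drivers, changed, truth


# ---------------------------------------------------------------------------
# Independent brute-force oracles (kept free of the package's fast paths)
# ---------------------------------------------------------------------------

def floodfill_patches(values, mask, connectivity):
    """Recursive flood-fill patch tally: per class (count, cells, exposed edges).

    Deliberately naive: explicit stack DFS over the raster, no scipy.
    """
    nrow, ncol = values.shape
    seen = np.zeros((nrow, ncol), dtype=bool)
    if connectivity == 4:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        steps = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    out = {}
    for r in range(nrow):
        for c in range(ncol):
            if mask[r, c] or seen[r, c]:
                continue
            code = values[r, c]
            if code not in out:
                out[code] = [0, 0, 0]
            seen[r, c] = True
            out[code][0] += 1
            stack = [(r, c)]
            while stack:
                rr, cc = stack.pop()
                out[code][1] += 1
                for dr, dc in [(-1, 0), (1, 0), (0, -1), (0, 1)]:
                    nr, nc = rr + dr, cc + dc
                    if not (0 <= nr < nrow and 0 <= nc < ncol) or mask[nr, nc] or values[nr, nc] != code:
                        out[code][2] += 1
                for dr, dc in steps:
                    nr, nc = rr + dr, cc + dc
                    if 0 <= nr < nrow and 0 <= nc < ncol and not mask[nr, nc] and not seen[nr, nc] and values[nr, nc] == code:
                        seen[nr, nc] = True
                        stack.append((nr, nc))
    return {k: tuple(v) for k, v in out.items()}


def brute_force_jenks(values, n_classes):
    """Minimum within-class SSE over all contiguous partitions, by enumeration."""
    import itertools

    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)

    def sse(seg):
        return float(((seg - seg.mean()) ** 2).sum())

    best = (np.inf, None)
    for cuts in itertools.combinations(range(1, n), n_classes - 1):
        bounds = (0, *cuts, n)
        total = sum(sse(x[a:b]) for a, b in zip(bounds[:-1], bounds[1:]))
        if total < best[0]:
            best = (total, cuts)
    return best
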