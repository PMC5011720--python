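"""Independent reference implementations used as test oracles."""

import numpy as np
import pandas as pd


def grid_search_oracle(data: pd.DataFrame, step: float = 0.01):
    """Exhaustive ML over ACE variance shares at fixed mean zero.

    For each (a2, c2) grid point the pair correlation structure is fixed and
    the total variance has the closed-form ML solution
    v_hat = sum_i x_i' Sigma0_i^{-1} x_i / (2 n), so the search enumerates
    the whole share simplex independently of any quasi-Newton machinery.
    Returns (loglik, a2, c2) of the best grid point.
    """
    mz = data[data.zygosity == "MZ"][["trait1_twin1", "trait1_twin2"]].to_numpy()
    dz = data[data.zygosity == "DZ"][["trait1_twin1", "trait1_twin2"]].to_numpy()
    n = len(mz) + len(dz)
    best = None
    grid = np.arange(0.0, 1.0 + step / 2, step)
    for a2 in grid:
        for c2 in grid[grid <= 1.0 - a2 + 1e-12]:
            q = 0.0
            logdet = 0.0
            ok = True
            for X, ra in ((mz, 1.0), (dz, 0.5)):
                r = ra * a2 + c2
                det = 1.0 - r * r
                if det <= 1e-12:
                    ok = False
                    break
                inv = np.array([[1.0, -r], [-r, 1.0]]) / det
                q += np.einsum("ij,jk,ik->", X, inv, X)
                logdet += len(X) * np.log(det)
            if not ok:
                continue
            v_hat = q / (2.0 * n)
            ll = -0.5 * (2 * n * np.log(2 * np.pi) + 2 * n * np.log(v_hat)
                         + logdet + q / v_hat)
            if best is None or ll > best[0]:
                best = (ll, a2, c2)
    return best


def brute_force_touches(tractogram, mask_vol) -> np.ndarray:
    """Per-point voxel-lookup streamline/mask intersection oracle."""
    inv = np.linalg.inv(tractogram.affine)
    shape = mask_vol.data.shape
    out = []
    for sl in tractogram.streamlines:
        hit = False
        for p in sl:
            v = inv[:3, :3] @ p + inv[:3, 3]
            ijk = tuple(int(np.sign(c) * np.floor(abs(c) + 0.5)) for c in v)
            if all(0 <= ijk[d] < shape[d] for d in range(3)):
                if mask_vol.data[ijk] > 0:
                    hit = True
                    break
        out.append(hit)
    return np.array(out)


def double_entry_correlation(pairs: np.ndarray) -> float:
    """Twin intraclass correlation via the double-entry Pearson estimator."""
    x = np.concatenate([pairs[:, 0], pairs[:, 1]])
    y = np.concatenate([pairs[:, 1], pairs[:, 0]])
    return float(np.corrcoef(x, y)[0, 1])
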