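"""Independent reference computations used to check the implementation."""

import numpy as np

# JPEG zigzag scan of an 8x8 block, written out literally.
ZIGZAG_8X8 = [
    (0, 0), (0, 1), (1, 0), (2, 0), (1, 1), (0, 2), (0, 3), (1, 2),
    (2, 1), (3, 0), (4, 0), (3, 1), (2, 2), (1, 3), (0, 4), (0, 5),
    (1, 4), (2, 3), (3, 2), (4, 1), (5, 0), (6, 0), (5, 1), (4, 2),
    (3, 3), (2, 4), (1, 5), (0, 6), (0, 7), (1, 6), (2, 5), (3, 4),
    (4, 3), (5, 2), (6, 1), (7, 0), (7, 1), (6, 2), (5, 3), (4, 4),
    (3, 5), (2, 6), (1, 7), (2, 7), (3, 6), (4, 5), (5, 4), (6, 3),
    (7, 2), (7, 3), (6, 4), (5, 5), (4, 6), (3, 7), (4, 7), (5, 6),
    (6, 5), (7, 4), (7, 5), (6, 6), (5, 7), (6, 7), (7, 6), (7, 7),
]


def naive_dct2(block):
    """Orthonormal 2-D DCT-II evaluated from the definition by quadruple loop."""
    block = np.asarray(block, float)
    n = block.shape[0]
    out = np.zeros((n, n))
    for u in range(n):
        for v in range(n):
            cu = np.sqrt(1 / n) if u == 0 else np.sqrt(2 / n)
            cv = np.sqrt(1 / n) if v == 0 else np.sqrt(2 / n)
            acc = 0.0
            for x in range(n):
                for y in range(n):
                    acc += block[x, y] * np.cos((2 * x + 1) * u * np.pi / (2 * n)) * np.cos(
                        (2 * y + 1) * v * np.pi / (2 * n)
                    )
            out[u, v] = cu * cv * acc
    return out


def oracle_bq(block, epsilon=1e-12, cap=1e12):
    """Block quality from the naive DCT and the literal zigzag table."""
    coeffs = naive_dct2(block)
    energies = np.array([coeffs[r, c] ** 2 for r, c in ZIGZAG_8X8])
    low = energies[1:32].sum()
    high = energies[32:64].sum()
    return min(high / (low + epsilon), cap)
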