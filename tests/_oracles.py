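"""Independent brute-force oracles used by the tests.

These deliberately share no code with the package: the watershed oracle
simulates flooding by exhaustively scanning a plain list for the next
pixel to expand instead of using a priority queue.
"""

import numpy as np

EIGHT = ((-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1))


def naive_flood(gradient, markers):
    """Level-by-level flooding by exhaustive minimum search.

    Same contract as the priority-flood: marker pixels start at their
    gradient height in row-major order; the pending entry with the smallest
    (height, insertion sequence) expands next and labels its unlabeled
    8-neighbors at max(own height, expander height).
    """
    grad = np.asarray(gradient, dtype=float)
    h, w = grad.shape
    labels = np.asarray(markers, dtype=int).copy()
    pending = []
    seq = 0
    for r in range(h):
        for c in range(w):
            if labels[r, c]:
                pending.append([grad[r, c], seq, r, c])
                seq += 1
    while pending:
        k = min(range(len(pending)), key=lambda i: (pending[i][0], pending[i][1]))
        height, _, r, c = pending.pop(k)
        for dr, dc in EIGHT:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and labels[rr, cc] == 0:
                labels[rr, cc] = labels[r, c]
                pending.append([max(grad[rr, cc], height), seq, rr, cc])
                seq += 1
    return labels


def random_flood_instance(rng, max_side=8, n_markers_range=(2, 4)):
    """One random small watershed problem: (gradient, marker map)."""
    h = int(rng.integers(2, max_side + 1))
    w = int(rng.integers(2, max_side + 1))
    # Small integer heights force plenty of ties.
    grad = rng.integers(0, 4, size=(h, w)).astype(float)
    n_markers = int(rng.integers(n_markers_range[0], n_markers_range[1] + 1))
    markers = np.zeros((h, w), dtype=np.int32)
    flat = rng.choice(h * w, size=n_markers, replace=False)
    for lab, i in enumerate(flat, start=1):
        markers[np.unravel_index(i, (h, w))] = lab
    return grad, markers
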