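"""Plain-text matrix I/O: first line N, then N rows of N entries."""
from __future__ import annotations

import numpy as np


def read_matrix(text: str) -> np.ndarray:
    tokens = text.split()
    if not tokens:
        raise ValueError("empty matrix content")
    n = int(tokens[0])
    vals = [float(t) for t in tokens[1:]]
    if len(vals) != n * n:
        raise ValueError(f"expected {n * n} entries for an {n}x{n} "
                         f"matrix, found {len(vals)}")
    return np.array(vals).reshape(n, n)


def write_matrix(M: np.ndarray) -> str:
    n = M.shape[0]
    rows = [" ".join(f"{x:.17g}" for x in row) for row in M]
    return f"{n}\n" + "\n".join(rows) + "\n"
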