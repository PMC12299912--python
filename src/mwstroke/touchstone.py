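"""Minimal Touchstone v1 reader/writer for single-frequency n-port S-matrices.

Covers exactly the interchange need of this package: one frequency point,
real/imaginary (RI) data format, Hz units, 50-ohm reference.  Data lines
follow the v1 multiport layout: each matrix row starts on a new line with at
most four complex pairs per line; the frequency leads the first line.
"""

from __future__ import annotations

import numpy as np

from .forward import SMatrix

_OPTION_LINE = "# Hz S RI R 50"


def write_touchstone(path, smatrix: SMatrix, comment: str | None = None) -> None:
    """Write a single-frequency ``.sNp`` file (RI format, Hz, 50 ohm)."""
    S = smatrix.entries
    n = smatrix.n_ports
    lines = []
    if comment:
        for c in comment.splitlines():
            lines.append(f"! {c}")
    lines.append(f"! {n}-port single-frequency S-matrix")
    lines.append(_OPTION_LINE)
    for i in range(n):
        prefix = f"{smatrix.frequency:.9e}" if i == 0 else ""
        row = S[i]
        for start in range(0, n, 4):
            chunk = row[start : start + 4]
            # 17 significant digits: float64 -> decimal -> float64 is exact
            nums = " ".join(f"{z.real: .16e} {z.imag: .16e}" for z in chunk)
            lines.append(f"{prefix} {nums}".strip() if start == 0 else f"  {nums}")
            prefix = ""
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_touchstone(path, n_ports: int = 10, reciprocity_tol: float = 1e-6) -> SMatrix:
    """Read a single-frequency ``.sNp`` file written in RI format.

    Tolerant to line wrapping: all numeric tokens after the option line are
    concatenated; the first is the frequency, the next ``2*n^2`` the matrix
    entries in row-major (real, imag) pairs.
    """
    tokens: list[float] = []
    saw_options = False
    with open(path) as fh:
        for raw in fh:
            line = raw.split("!", 1)[0].strip()
            if not line:
                continue
            if line.startswith("#"):
                opts = line.upper().split()
                if "RI" not in opts or "HZ" not in opts:
                    raise ValueError(
                        f"unsupported Touchstone options {line!r}; need Hz + RI"
                    )
                saw_options = True
                continue
            tokens.extend(float(t) for t in line.split())
    if not saw_options:
        raise ValueError("missing Touchstone option line ('# Hz S RI R 50')")
    expected = 1 + 2 * n_ports * n_ports
    if len(tokens) != expected:
        raise ValueError(
            f"expected {expected} numbers for a single-frequency "
            f"{n_ports}-port file, found {len(tokens)}"
        )
    freq = tokens[0]
    vals = np.asarray(tokens[1:], float).reshape(n_ports, n_ports, 2)
    S = SMatrix(vals[..., 0] + 1j * vals[..., 1], freq)
    S.check_reciprocity(reciprocity_tol)
    return S
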