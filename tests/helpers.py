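"""Test-only helpers: a minimal 16-bit EDF writer for round-trip fixtures.

No installed library writes EDF, so the test suite emits the simplest valid
continuous EDF: one header, per-signal subheaders, 1-second data records of
little-endian int16 with per-channel physical scaling.
"""

import numpy as np


def _field(value, width) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_minimal_edf(path, data: np.ndarray, fs: float, labels: list[str]) -> None:
    n_sig = data.shape[0]
    spr = int(round(fs))                      # samples per 1-s record
    n_rec = data.shape[1] // spr
    data = data[:, :n_rec * spr]
    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    pmax = np.where(pmax > pmin, pmax, pmin + 1.0)
    dmin, dmax = -32768, 32767

    header = b"".join([
        _field("0", 8), _field("X X X X", 80), _field("Startdate X X X X", 80),
        _field("01.01.20", 8), _field("00.00.00", 8),
        _field(256 * (1 + n_sig), 8), _field("", 44),
        _field(n_rec, 8), _field(1, 8), _field(n_sig, 4),
    ])
    sig = b"".join([
        b"".join(_field(l, 16) for l in labels),
        b"".join(_field("", 80) for _ in labels),
        b"".join(_field("uV", 8) for _ in labels),
        b"".join(_field(f"{v:.3f}", 8) for v in pmin),
        b"".join(_field(f"{v:.3f}", 8) for v in pmax),
        b"".join(_field(dmin, 8) for _ in labels),
        b"".join(_field(dmax, 8) for _ in labels),
        b"".join(_field("", 80) for _ in labels),
        b"".join(_field(spr, 8) for _ in labels),
        b"".join(_field("", 32) for _ in labels),
    ])
    scale = (pmax - pmin) / (dmax - dmin)
    digital = np.round((data - pmin[:, None]) / scale[:, None] + dmin).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header + sig)
        for r in range(n_rec):
            for c in range(n_sig):
                fh.write(digital[c, r * spr:(r + 1) * spr].tobytes())
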