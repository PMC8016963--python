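"""Small shared helpers: id normalization, seed fan-out, correlation p-values."""

from __future__ import annotations

import zlib

import numpy as np
from scipy import stats


def norm_id(s: str) -> str:
    """Canonical form used when matching gene/drug identifiers across files:
    whitespace-trimmed, case-folded. No alias resolution is attempted."""
    return s.strip().casefold()


def fanout_seed(master_seed: int, *labels: str | int) -> int:
    """Derive a per-stage / per-drug seed from the master seed.

    CRC32 of the label string is mixed into the master seed so that adding a
    drug to a run never perturbs another drug's random draws.  Result is kept
    below 2**31 so it is portable as a seed everywhere.
    """
    h = zlib.crc32("|".join(str(x) for x in labels).encode("utf8"))
    return (int(master_seed) * 1000003 + h) % (2**31)


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r with a two-sided p-value from the t transform.

    Returns (0.0, 1.0) for degenerate (constant or too-short) inputs rather
    than raising, because callers treat "no linear signal" and "no evidence"
    identically.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3 or np.std(x) == 0 or np.std(y) == 0:
        return 0.0, 1.0
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(min(r, 1.0), -1.0)
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(min(p, 1.0))
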