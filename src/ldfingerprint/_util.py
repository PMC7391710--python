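"""Small numeric and I/O helpers shared across modules."""

from __future__ import annotations

import math
import os
import tempfile
from contextlib import contextmanager

import numpy as np
from scipy.special import logsumexp as _ln_logsumexp

LN10 = math.log(10.0)


def log10sumexp(a, axis=None):
    """Stable log10(sum(10**a)) along ``axis``.

    ``-inf`` entries are handled; an all ``-inf`` slice yields ``-inf``.
    """
    a = np.asarray(a, dtype=float)
    return _ln_logsumexp(a * LN10, axis=axis) / LN10


def phred_to_error(q: float) -> float:
    """Phred quality -> error probability, 10**(-q/10)."""
    return 10.0 ** (-q / 10.0)


@contextmanager
def atomic_write(path, mode="w"):
    """Write to a temp file in the destination directory, rename on success."""
    directory = os.path.dirname(os.path.abspath(path)) or "."
    fd, tmp = tempfile.mkstemp(dir=directory, prefix=".tmp-", suffix="~")
    try:
        with os.fdopen(fd, mode) as handle:
            yield handle
        os.replace(tmp, path)
    except BaseException:
        try:
            os.unlink(tmp)
        except OSError:
            pass
        raise
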