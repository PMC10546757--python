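"""Deterministic stand-ins for the random generator, used in fixed-point tests.

With all innovations zeroed, every Gibbs draw lands on its conditional
mean, so an iterated sweep is exactly Gauss–Seidel on the underlying
mixed-model equations — letting tests compare against dense solves.
"""

from __future__ import annotations

import numpy as np

__all__ = ["ZeroInnovationRNG"]


class ZeroInnovationRNG:
    """Generator stand-in whose normal draws are zero.

    ``chisquare(df)`` returns ``df`` (so scaled inverse-chi-square draws
    land on their scale parameter), ``random`` returns zeros (indicators
    always included) and ``beta`` returns the distribution mean.
    """

    def standard_normal(self, size=None):
        return 0.0 if size is None else np.zeros(size)

    def normal(self, loc=0.0, scale=1.0, size=None):
        return loc if size is None else np.full(size, loc)

    def random(self, size=None):
        return 0.0 if size is None else np.zeros(size)

    def chisquare(self, df, size=None):
        return df if size is None else np.full(size, df)

    def beta(self, a, b, size=None):
        v = a / (a + b)
        return v if size is None else np.full(size, v)
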