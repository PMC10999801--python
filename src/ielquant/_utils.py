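"""Small shared helpers: seeding and half-up rounding."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np


def spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Derive ``n`` independent generators from one master seed.

    Each stage of the generator (geometry, nuclei, rendering noise) draws
    from its own substream so that, e.g., changing the noise level never
    perturbs the tissue geometry.
    """
    return [np.random.Generator(np.random.PCG64(s)) for s in np.random.SeedSequence(seed).spawn(n)]


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round with ties going away from zero at the given decimal place.

    Python's built-in ``round`` is banker's rounding; frequency tables and
    band thicknesses are reported with conventional half-up rounding.
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
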