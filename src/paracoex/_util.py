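import numpy as np


def round_half_away(x: float) -> int:
    """Round to the nearest integer, ties away from zero.

    Species counts are reported with this rule rather than banker's
    rounding, so e.g. 59.5 -> 60 and -0.5 -> -1.
    """
    return int(np.sign(x) * np.floor(np.abs(x) + 0.5))


def child_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent 31-bit child seeds from one master seed.

    Uses :class:`numpy.random.SeedSequence` spawning so every pipeline
    stage gets its own reproducible stream.
    """
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n)]
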