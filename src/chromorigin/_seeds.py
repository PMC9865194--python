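"""Deterministic seed derivation.

Every stochastic stage derives its RNG seed from a single user-facing
integer plus a few context tokens (stage name, repeat index, subset size,
...), via a splitmix64-style mix.  Adding new stages or sizes therefore
never perturbs the streams of existing ones, and all derived seeds fit in
31 bits so they are valid for every downstream library.
"""

from __future__ import annotations

_MASK = (1 << 64) - 1


def _splitmix64(x: int) -> int:
    x = (x + 0x9E3779B97F4A7C15) & _MASK
    x = ((x ^ (x >> 30)) * 0xBF58476D1CE4E5B9) & _MASK
    x = ((x ^ (x >> 27)) * 0x94D049BB133111EB) & _MASK
    return x ^ (x >> 31)


def derive_seed(seed: int, *tokens) -> int:
    """Mix ``seed`` with context tokens into a 31-bit seed."""
    x = int(seed) & _MASK
    for tok in tokens:
        if isinstance(tok, str):
            for ch in tok.encode():
                x = _splitmix64(x ^ ch)
        else:
            x = _splitmix64(x ^ (int(tok) & _MASK))
    return _splitmix64(x) & 0x7FFFFFFF
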