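"""Mutation-centered sequence windows.

The regressor does not read whole chains: each sample is a 181-residue
window of the *mutant* sequence centred on the substituted residue (90
residues of flank on each side).  Near a terminus the window slides to keep
181 real residues; chains shorter than 181 are taken whole and the
embedding rows are later zero-padded to the target length.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["WindowConfig", "WindowedSample", "apply_mutation", "extract_window"]


@dataclass(frozen=True)
class WindowConfig:
    flank: int = 90

    def __post_init__(self):
        if self.flank < 0:
            raise ValueError("flank must be non-negative")

    @property
    def target_len(self) -> int:
        return 2 * self.flank + 1


@dataclass(frozen=True)
class WindowedSample:
    window_seq: str
    local_index: int  # 0-based position of the mutated residue in window_seq
    global_start: int  # 1-based start of the window in the full chain
    pad_len: int  # zero rows appended downstream to reach target_len

    def __post_init__(self):
        if not 0 <= self.local_index < len(self.window_seq):
            raise ValueError("local_index outside window")


def apply_mutation(sequence: str, position: int, wt: str, mut: str) -> str:
    """Substitute ``mut`` for ``wt`` at 1-based ``position``.

    Raises if the sequence does not carry ``wt`` there — that always signals
    a record/sequence inconsistency upstream.
    """
    if not 1 <= position <= len(sequence):
        raise ValueError(f"position {position} out of range 1..{len(sequence)}")
    if wt == mut:
        raise ValueError("identity substitution is not a missense mutation")
    found = sequence[position - 1]
    if found != wt:
        raise ValueError(
            f"sequence has {found} at position {position}, expected wild-type {wt}"
        )
    return sequence[: position - 1] + mut + sequence[position:]


def extract_window(sequence: str, position: int,
                   config: WindowConfig = WindowConfig()) -> WindowedSample:
    """Extract the mutation-centered window around 1-based ``position``.

    For sequences of at least ``target_len`` residues the window has exactly
    ``target_len`` residues: centred when both flanks fit, otherwise shifted
    to stay inside the sequence (the mutation site then sits off-centre).
    Shorter sequences are returned whole with ``pad_len`` recording the
    deficit.
    """
    n = len(sequence)
    if not 1 <= position <= n:
        raise ValueError(f"position {position} out of range 1..{n}")
    target = config.target_len
    if n < target:
        return WindowedSample(sequence, position - 1, 1, target - n)
    start = position - config.flank  # 1-based
    start = max(1, min(start, n - target + 1))
    window = sequence[start - 1 : start - 1 + target]
    return WindowedSample(window, position - start, start, 0)
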