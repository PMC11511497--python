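"""Adjacent stimulation/measurement protocol and the raw-data packing codec.

The device drives a 1 mA RMS current between adjacent electrodes on a
16-electrode ring and measures differential voltages on every adjacent pair
not touching a drive electrode, giving ``n * (n - 3)`` combinations per
frame (208 for n = 16).

The drive sequence alternates polarity so that odd electrodes only ever
source current and even electrodes only ever sink it: pattern 1 is
(+E1, -E2), pattern 2 (+E3, -E2), pattern 3 (+E3, -E4), ... , pattern 16
(+E1, -E16).  Measurement pairs for each pattern step through the same
alternating cycle of adjacent pairs, skipping the three pairs that share an
electrode with the drive pair.

Each 64-sample ADC burst is packed as 16-bit words: the measurement slot
(0-12, position within the current stimulation pattern) in the four most
significant bits and the 12-bit ADC code in the rest.  Words are emitted
high byte first so a hex dump reads slot-then-code.  Slot values 13-15 are
reserved and mark a word as sync-invalid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ProtocolError",
    "CodecError",
    "ProtocolSpec",
    "PackedMeasurement",
    "MUX_TABLE",
    "SAMPLES_PER_MEASUREMENT",
    "BYTES_PER_MEASUREMENT",
    "build_protocol",
    "mux_select",
    "pack_measurement",
    "unpack_measurement",
    "pack_stream",
    "stim_pattern_matrix",
]

SAMPLES_PER_MEASUREMENT = 64
BYTES_PER_MEASUREMENT = 2 * SAMPLES_PER_MEASUREMENT

#: slot values 13-15 never occur in a valid stream (13 slots per pattern)
N_SLOTS = 13
MAX_CODE = 0x0FFF


class ProtocolError(ValueError):
    """Invalid protocol size or electrode pair."""


class CodecError(ValueError):
    """Malformed packed byte stream."""


def _alternating_pairs(n: int) -> list[tuple[int, int]]:
    """The cyclic sequence of adjacent (source-like, sink-like) pairs.

    Pair k (1-based) is (k, k+1) for odd k and (k+1, k) for even k, with
    wrap-around, so the first element is always odd and the second even.
    """
    pairs = []
    for k in range(1, n + 1):
        if k % 2 == 1:
            a, b = k, k % n + 1
        else:
            a, b = k % n + 1, k
        pairs.append((a, b))
    return pairs


@dataclass(frozen=True)
class ProtocolSpec:
    """Full stimulation/measurement schedule for one frame."""

    n_electrodes: int
    stim_pairs: tuple[tuple[int, int], ...]
    meas_pairs: tuple[tuple[tuple[int, int], ...], ...]

    @property
    def n_patterns(self) -> int:
        return len(self.stim_pairs)

    @property
    def n_measurements(self) -> int:
        return sum(len(m) for m in self.meas_pairs)

    @property
    def meas_per_pattern(self) -> int:
        return self.n_electrodes - 3

    def to_frame(self) -> pd.DataFrame:
        """Flat table (pattern, source, sink, slot, meas_first, meas_second)."""
        rows = []
        for p, ((src, snk), meas) in enumerate(
            zip(self.stim_pairs, self.meas_pairs), start=1
        ):
            for slot, (a, b) in enumerate(meas):
                rows.append((p, src, snk, slot, a, b))
        return pd.DataFrame(
            rows,
            columns=["pattern", "source", "sink", "slot", "meas_first", "meas_second"],
        )


def build_protocol(n_electrodes: int = 16) -> ProtocolSpec:
    """Build the modified-Sheffield adjacent protocol for a ring of electrodes.

    Raises :class:`ProtocolError` for odd or too-small electrode counts.
    """
    if n_electrodes < 4 or n_electrodes % 2 != 0:
        raise ProtocolError(
            f"protocol requires an even electrode count >= 4, got {n_electrodes}"
        )
    pairs = _alternating_pairs(n_electrodes)
    meas_lists = []
    for src, snk in pairs:
        drive = {src, snk}
        meas = tuple(p for p in pairs if not drive & set(p))
        meas_lists.append(meas)
    return ProtocolSpec(
        n_electrodes=n_electrodes,
        stim_pairs=tuple(pairs),
        meas_pairs=tuple(meas_lists),
    )


#: Current-multiplexer selector map: adjacent pair -> (selector A, selector B).
#: Selector A addresses the odd electrodes, selector B the even ones; the
#: values are the board's own channel coding, not a closed formula.
MUX_TABLE: dict[frozenset, tuple[int, int]] = {
    frozenset(p): sel
    for p, sel in [
        ((1, 2), (0, 0)),
        ((2, 3), (0, 1)),
        ((3, 4), (1, 1)),
        ((4, 5), (1, 2)),
        ((5, 6), (2, 2)),
        ((6, 7), (2, 3)),
        ((7, 8), (3, 3)),
        ((8, 9), (3, 4)),
        ((9, 10), (4, 4)),
        ((10, 11), (4, 5)),
        ((11, 12), (5, 5)),
        ((12, 13), (5, 6)),
        ((13, 14), (6, 6)),
        ((14, 15), (6, 7)),
        ((15, 16), (7, 7)),
        ((16, 1), (7, 0)),
    ]
}


def mux_select(pair: tuple[int, int]) -> tuple[int, int]:
    """Selector codes (A, B) for an adjacent electrode pair (either order)."""
    key = frozenset(pair)
    try:
        return MUX_TABLE[key]
    except KeyError:
        raise ProtocolError(f"{tuple(pair)} is not an adjacent electrode pair") from None


@dataclass(frozen=True)
class PackedMeasurement:
    """One 64-sample ADC burst tagged with its slot within the pattern."""

    slot_index: int
    samples: np.ndarray = field(repr=False)

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=np.uint16)
        object.__setattr__(self, "samples", samples)
        if not 0 <= self.slot_index < N_SLOTS:
            raise CodecError(f"slot index {self.slot_index} outside 0-12")
        if samples.shape != (SAMPLES_PER_MEASUREMENT,):
            raise CodecError(
                f"expected {SAMPLES_PER_MEASUREMENT} samples, got {samples.shape}"
            )
        if samples.max(initial=0) > MAX_CODE:
            raise CodecError("ADC code exceeds 12 bits")

    def __eq__(self, other):
        return (
            isinstance(other, PackedMeasurement)
            and self.slot_index == other.slot_index
            and np.array_equal(self.samples, other.samples)
        )


def pack_measurement(m: PackedMeasurement) -> bytes:
    """Encode one measurement as 64 big-endian 16-bit words (128 bytes)."""
    words = (np.uint16(m.slot_index) << 12) | m.samples.astype(np.uint16)
    return words.astype(">u2").tobytes()


def unpack_measurement(data: bytes) -> PackedMeasurement:
    """Inverse of :func:`pack_measurement`; rejects framing/slot violations."""
    if len(data) % 2 != 0:
        raise CodecError(f"odd byte count {len(data)}: not a whole number of words")
    if len(data) != BYTES_PER_MEASUREMENT:
        raise CodecError(
            f"expected {BYTES_PER_MEASUREMENT} bytes per measurement, got {len(data)}"
        )
    words = np.frombuffer(data, dtype=">u2")
    slots = words >> 12
    if slots.min() != slots.max():
        raise CodecError("slot index changes inside a measurement")
    slot = int(slots[0])
    if slot >= N_SLOTS:
        raise CodecError(f"reserved slot value {slot}: sync-invalid word")
    return PackedMeasurement(slot_index=slot, samples=(words & MAX_CODE))


def pack_stream(slots: np.ndarray, samples: np.ndarray) -> bytes:
    """Pack many measurements at once.

    ``slots`` has shape (n,), ``samples`` (n, 64); returned bytes concatenate
    the per-measurement encodings in order.
    """
    slots = np.asarray(slots, dtype=np.uint16)
    samples = np.asarray(samples, dtype=np.uint16)
    if samples.ndim != 2 or samples.shape[1] != SAMPLES_PER_MEASUREMENT:
        raise CodecError(f"samples must be (n, 64), got {samples.shape}")
    if slots.shape[0] != samples.shape[0]:
        raise CodecError("slots/samples length mismatch")
    if slots.max(initial=0) >= N_SLOTS or samples.max(initial=0) > MAX_CODE:
        raise CodecError("field overflow while packing")
    words = (slots[:, None] << 12) | samples
    return words.astype(">u2").tobytes()


def stim_pattern_matrix(spec: ProtocolSpec) -> np.ndarray:
    """Signed drive matrix, +1 at the source and -1 at the sink per column."""
    mat = np.zeros((spec.n_electrodes, spec.n_patterns), dtype=int)
    for k, (src, snk) in enumerate(spec.stim_pairs):
        mat[src - 1, k] = 1
        mat[snk - 1, k] = -1
    return mat
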