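"""Markov Brains: genome-encoded logic-gate networks.

A Markov Brain is a network of logic gates wired over a fixed set of binary
nodes: 7 sensor nodes (indices 0-6), 9 hidden nodes (7-15) and 3 actuator
nodes (16-18).  The wiring and the gates' truth/probability tables are read
out of a variable-length genome of byte-valued sites, so the whole
controller is evolvable by point mutation, segment deletion and segment
duplication.  Hidden nodes give the brain recurrent memory: whatever a gate
writes into a hidden node this update is readable by every gate on the next
update.

Gene layout
-----------
A gene starts at every occurrence of the start codon ``(42, 213)``.  The
sites that follow (read circularly) determine, in order, each value taken
modulo its valid range:

====================  =======================================================
site(s)               meaning
====================  =======================================================
1                     gate kind: even = deterministic, odd = probabilistic
1                     number of inputs, 1-4
1                     number of outputs, 1-4
4                     input node ids (first ``n_in`` used), mod 19
4                     output node ids (first ``n_out`` used), mod 19
per row               deterministic: 1 site per input pattern, the output bit
                      pattern (mod 2**n_out); probabilistic: 2**n_out sites
                      per input pattern, normalised into row probabilities
====================  =======================================================

Overlapping genes are allowed; a genome with no start codon decodes to an
empty brain that never acts.  When several gates write the same node in one
update the writes combine by OR.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .env import ActionGA, MoveGA

__all__ = [
    "N_SENSORS",
    "N_HIDDEN",
    "N_ACTUATORS",
    "N_NODES",
    "START_CODON",
    "Gate",
    "MutationRates",
    "random_genome",
    "decode",
    "encode_gate",
    "new_brain_state",
    "set_sensors",
    "brain_update",
    "actuate",
    "mutate",
    "describe_gates",
]

N_SENSORS = 7
N_HIDDEN = 9
N_ACTUATORS = 3
N_NODES = N_SENSORS + N_HIDDEN + N_ACTUATORS  # 19

SENSOR_SLICE = slice(0, N_SENSORS)
ACTUATOR_OFFSET = N_SENSORS + N_HIDDEN  # 16

START_CODON = (42, 213)
SITE_MAX = 256  # sites are bytes


@dataclass(frozen=True)
class Gate:
    """One decoded logic gate.

    ``table`` is, for a deterministic gate, an int array of shape
    ``(2**n_in,)`` holding the output bit pattern per input pattern; for a
    probabilistic gate, a float array of shape ``(2**n_in, 2**n_out)`` whose
    rows are probability distributions over output patterns.
    """

    probabilistic: bool
    inputs: tuple[int, ...]
    outputs: tuple[int, ...]
    table: np.ndarray

    def __post_init__(self):
        if not all(0 <= n < N_NODES for n in self.inputs + self.outputs):
            raise ValueError("gate wired to a node outside 0..18")
        if self.probabilistic:
            rows = np.asarray(self.table, dtype=float)
            if not np.allclose(rows.sum(axis=1), 1.0):
                raise ValueError("probabilistic rows must sum to 1")
        # precompute cumulative rows for fast sampling
        object.__setattr__(
            self,
            "_cum",
            np.cumsum(self.table, axis=1) if self.probabilistic else None,
        )


def random_genome(
    length: int, rng: np.random.Generator, n_start_codons: int = 12
) -> list[int]:
    """Uniform random genome of byte sites, seeded with start codons.

    A uniform byte string of a few hundred sites contains a start codon
    only with probability ~L/65536, so freshly generated genomes would be
    empty brains; sprinkling ``n_start_codons`` codons at random positions
    gives generation 0 functional (if arbitrary) gates for selection to
    act on.
    """
    sites = rng.integers(0, SITE_MAX, size=length)
    if n_start_codons:
        pos = rng.integers(0, max(1, length - 1), size=n_start_codons)
        sites[pos] = START_CODON[0]
        sites[(pos + 1) % length] = START_CODON[1]
    return sites.tolist()


def _read(sites: Sequence[int], pos: int, n: int) -> list[int]:
    L = len(sites)
    return [sites[(pos + k) % L] for k in range(n)]


def decode(genome: Sequence[int], max_gates: int | None = None) -> list[Gate]:
    """Decode a genome into its gate list (a pure function of the genome).

    The codon scan is linear over site pairs; gene bodies are read
    circularly so genes near the end of the genome are still complete.
    ``max_gates`` optionally caps the brain size (scanning stops early).
    """
    gates: list[Gate] = []
    L = len(genome)
    for i in range(L - 1):
        if genome[i] != START_CODON[0] or genome[i + 1] != START_CODON[1]:
            continue
        p = i + 2
        kind, n_in_raw, n_out_raw = _read(genome, p, 3)
        probabilistic = bool(kind % 2)
        n_in = 1 + (n_in_raw % 4)
        n_out = 1 + (n_out_raw % 4)
        ins = tuple(s % N_NODES for s in _read(genome, p + 3, 4)[:n_in])
        outs = tuple(s % N_NODES for s in _read(genome, p + 7, 4)[:n_out])
        n_rows = 1 << n_in
        if probabilistic:
            raw = np.array(_read(genome, p + 11, n_rows * (1 << n_out)), dtype=float)
            raw = raw.reshape(n_rows, 1 << n_out)
            sums = raw.sum(axis=1, keepdims=True)
            uniform = np.full_like(raw, 1.0 / raw.shape[1])
            table = np.where(sums > 0, raw / np.where(sums > 0, sums, 1.0), uniform)
        else:
            table = np.array(
                [s % (1 << n_out) for s in _read(genome, p + 11, n_rows)], dtype=np.int64
            )
        gates.append(Gate(probabilistic, ins, outs, table))
        if max_gates is not None and len(gates) >= max_gates:
            break
    return gates


def encode_gate(
    inputs: Sequence[int], outputs: Sequence[int], table: Sequence[int]
) -> list[int]:
    """Sites for one deterministic gene (the inverse of :func:`decode` for
    the deterministic case); handy for building brains by hand."""
    n_in, n_out = len(inputs), len(outputs)
    if not (1 <= n_in <= 4 and 1 <= n_out <= 4):
        raise ValueError("1-4 inputs and outputs")
    if len(table) != 1 << n_in:
        raise ValueError("one table entry per input pattern")
    sites = [START_CODON[0], START_CODON[1], 0, n_in - 1, n_out - 1]
    sites += list(inputs) + [0] * (4 - n_in)
    sites += list(outputs) + [0] * (4 - n_out)
    sites += [int(t) % (1 << n_out) for t in table]
    return sites


def new_brain_state() -> list[int]:
    """All-zero node vector (19 binary values)."""
    return [0] * N_NODES


def set_sensors(state: list[int], bits: Sequence[int]) -> None:
    """Overwrite the sensor nodes from a 7-bit observation."""
    if len(bits) != N_SENSORS:
        raise ValueError("expected 7 sensor bits")
    state[SENSOR_SLICE] = [int(b) & 1 for b in bits]


def brain_update(
    state: Sequence[int], gates: Sequence[Gate], rng: np.random.Generator
) -> list[int]:
    """One synchronous network update.

    Every gate reads the pre-update node vector and writes into a zeroed
    post-update vector; writes to the same node combine by OR.  Sensor
    values are consumed this update (the caller overwrites them before the
    next).  Deterministic gates never consult ``rng``.
    """
    new = [0] * N_NODES
    for g in gates:
        pattern = 0
        for k, node in enumerate(g.inputs):
            if state[node]:
                pattern |= 1 << k
        if g.probabilistic:
            out_pattern = int(np.searchsorted(g._cum[pattern], rng.random(), side="right"))
        else:
            out_pattern = int(g.table[pattern])
        for m, node in enumerate(g.outputs):
            if out_pattern >> m & 1:
                new[node] = 1
    return new


def actuate(state: Sequence[int]) -> ActionGA:
    """Read the three actuator nodes into a GA action.

    Bits 16 (high) and 17 (low) encode the movement — 00 NOTHING, 01 LEFT,
    10 RIGHT, 11 FORWARD — and bit 18 is the beep.
    """
    code = (state[ACTUATOR_OFFSET] << 1) | state[ACTUATOR_OFFSET + 1]
    return ActionGA(MoveGA(code), bool(state[ACTUATOR_OFFSET + 2]))


@dataclass(frozen=True)
class MutationRates:
    """Per-offspring mutation parameters.

    ``p_point`` applies per site (resample a uniform byte); ``p_delete`` and
    ``p_duplicate`` apply once per genome, removing or copy-inserting a
    contiguous segment whose length is uniform in ``segment_range``.  An
    operation that would push the genome outside ``length_bounds`` is
    skipped.
    """

    p_point: float = 0.005
    p_delete: float = 0.02
    p_duplicate: float = 0.05
    segment_range: tuple[int, int] = (16, 512)
    length_bounds: tuple[int, int] = (1000, 20000)


def mutate(
    genome: Sequence[int], rates: MutationRates, rng: np.random.Generator
) -> list[int]:
    """Return a mutated copy of ``genome`` (the input is never modified)."""
    g = np.asarray(genome, dtype=np.int64)
    if rates.p_point > 0:
        hits = rng.random(g.size) < rates.p_point
        n = int(hits.sum())
        if n:
            g = g.copy()
            g[hits] = rng.integers(0, SITE_MAX, size=n)
    out = g.tolist()
    lo, hi = rates.length_bounds
    if rates.p_delete > 0 and rng.random() < rates.p_delete:
        seg = int(rng.integers(rates.segment_range[0], rates.segment_range[1] + 1))
        seg = min(seg, len(out))
        if len(out) - seg >= lo:
            start = int(rng.integers(0, len(out) - seg + 1))
            del out[start : start + seg]
    if rates.p_duplicate > 0 and rng.random() < rates.p_duplicate:
        seg = int(rng.integers(rates.segment_range[0], rates.segment_range[1] + 1))
        seg = min(seg, len(out))
        if len(out) + seg <= hi:
            start = int(rng.integers(0, len(out) - seg + 1))
            insert_at = int(rng.integers(0, len(out) + 1))
            out[insert_at:insert_at] = out[start : start + seg]
    return out


def describe_gates(gates: Sequence[Gate]) -> str:
    """Human-readable gate listing for debugging evolved brains."""
    lines = []
    for i, g in enumerate(gates):
        kind = "prob" if g.probabilistic else "det"
        lines.append(f"gate {i} [{kind}] in={g.inputs} out={g.outputs}")
        for row, entry in enumerate(np.atleast_1d(g.table)):
            lines.append(f"  {row:0{len(g.inputs)}b} -> {entry}")
    return "\n".join(lines) if lines else "(empty brain)"
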