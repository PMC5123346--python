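"""Stochastic simulator of one-sided fractionation on the real line.

The fractionating genome copy is a finite interval of length ``G`` whose
points are initially all *visible* (undeleted).  Deletion proceeds in
discrete *sweeps*.  Within a sweep, a cursor moves along the concatenation
of the currently visible segments: it jumps ahead by an exponential spacing
with mean ``nu``, then deletes an exponential length with mean ``mu``, and
repeats until it leaves the visible extent.  Deleted (*invisible*) runs are
observable only through the intact second genome copy, which keeps a
length-preserving correspondence with the original coordinates.

Each invisible run is anchored by the deletion point at its left end, which
carries an event counter ``C(x)``: the number of deletion events merged
into the run.  A new deletion that swallows ``q`` pre-existing deletion
points with counters ``C(z_1..z_q)`` gets counter ``1 + sum C(z_i)``.

Because later genomes would otherwise shrink away, each sweep can be
followed by *replenishment*: visible material (with its flanking invisible
runs and their counters) is copied from a replicate trial and appended
until the visible length is back to ``G``.
"""

from __future__ import annotations

import math
import warnings
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .errors import ConfigurationError

VISIBLE = "visible"
INVISIBLE = "invisible"

__all__ = [
    "VISIBLE",
    "INVISIBLE",
    "SweepParams",
    "Segment",
    "GenomeState",
    "DeletionEvent",
    "SimConfig",
    "LengthSample",
    "FractionationResult",
    "new_genome",
    "validate_genome_state",
    "map_concat_to_original",
    "concat_coordinate",
    "apply_deletion",
    "run_sweep",
    "replenish",
    "run_fractionation",
    "collect_lengths",
    "overlap_histogram",
    "counter_census",
]


@dataclass(frozen=True)
class SweepParams:
    """Model parameters of one sweep.

    nu : mean of the exponential spacing between successive deletion
         points along visible coordinates (genome-length units).
    mu : mean of the exponential length deleted by a single event.

    Normally ``nu >> mu`` in applications, but the model does not require
    it and neither does this class.
    """

    nu: float
    mu: float

    def __post_init__(self):
        if not (self.nu > 0):
            raise ValueError(f"nu must be positive, got {self.nu}")
        if not (self.mu > 0):
            raise ValueError(f"mu must be positive, got {self.mu}")

    def spacing_density(self, x):
        """Density of the deletion-point spacing, Exponential(mean nu)."""
        x = np.asarray(x, dtype=float)
        return np.where(x >= 0, np.exp(-x / self.nu) / self.nu, 0.0)

    def length_density(self, a):
        """Density of a single deletion length, Exponential(mean mu)."""
        a = np.asarray(a, dtype=float)
        return np.where(a >= 0, np.exp(-a / self.mu) / self.mu, 0.0)


@dataclass(slots=True)
class Segment:
    """Half-open interval ``[start, end)`` in original coordinates.

    Invisible segments carry the event counter of the deletion point at
    their left end; visible segments carry no counter.
    """

    start: float
    end: float
    state: str
    counter: int | None = None

    @property
    def length(self) -> float:
        return self.end - self.start


@dataclass
class GenomeState:
    """Alternating visible/invisible segments on original coordinates."""

    segments: list[Segment]
    sweep_index: int = 0
    target_visible_length: float = 0.0

    def visible_length(self) -> float:
        return sum(s.length for s in self.segments if s.state == VISIBLE)

    def invisible_length(self) -> float:
        return sum(s.length for s in self.segments if s.state == INVISIBLE)

    def total_span(self) -> float:
        if not self.segments:
            return 0.0
        return self.segments[-1].end - self.segments[0].start

    def visible_segments(self) -> list[Segment]:
        return [s for s in self.segments if s.state == VISIBLE]

    def invisible_segments(self) -> list[Segment]:
        return [s for s in self.segments if s.state == INVISIBLE]

    def copy(self) -> "GenomeState":
        return GenomeState(
            [replace(s) for s in self.segments],
            self.sweep_index,
            self.target_visible_length,
        )


@dataclass(frozen=True)
class DeletionEvent:
    """Record of one deletion event.

    x_conc : deletion point in concatenated-visible coordinates.
    x_orig : the same point in original coordinates.
    a      : deletion length actually applied (a right-edge overhang is
             truncated at the visible extent).
    q      : number of pre-existing visible deletion points swallowed.
    swallowed_counters : their event counters; the merged run's counter is
             ``1 + sum(swallowed_counters)``.
    """

    x_conc: float
    x_orig: float
    a: float
    q: int
    swallowed_counters: tuple[int, ...] = ()

    def __post_init__(self):
        if self.q != len(self.swallowed_counters):
            raise ValueError("q must equal len(swallowed_counters)")

    @property
    def merged_counter(self) -> int:
        return 1 + sum(self.swallowed_counters)


@dataclass(frozen=True)
class SimConfig:
    """Experimental design of a fractionation run."""

    sweeps: int
    genome_length: float = 10_000.0
    replicates: int = 5
    seed: int = 0
    replenish: bool = True

    def __post_init__(self):
        if self.sweeps < 0:
            raise ValueError("sweeps must be non-negative")
        if not (self.genome_length > 0):
            raise ValueError("genome_length must be positive")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass
class LengthSample:
    """Pooled visible / invisible segment lengths at one sweep index."""

    visible: np.ndarray
    invisible: np.ndarray
    sweep_index: int

    def __post_init__(self):
        self.visible = np.asarray(self.visible, dtype=float)
        self.invisible = np.asarray(self.invisible, dtype=float)


def new_genome(genome_length: float) -> GenomeState:
    """Fresh, fully visible genome ``[0, G)`` at sweep index 0."""
    if not (genome_length > 0):
        raise ValueError("genome_length must be positive")
    return GenomeState(
        [Segment(0.0, float(genome_length), VISIBLE)],
        sweep_index=0,
        target_visible_length=float(genome_length),
    )


def validate_genome_state(state: GenomeState, tol: float = 1e-9) -> None:
    """Assert the structural invariants; raise ``ValueError`` on violation.

    Checks: non-empty, positive lengths, sortedness, contiguity (each end
    equals the next start), strict alternation of states, and counters
    present exactly on invisible segments with value >= 1.
    """
    segs = state.segments
    if not segs:
        raise ValueError("GenomeState has no segments")
    prev = None
    for k, s in enumerate(segs):
        if s.state not in (VISIBLE, INVISIBLE):
            raise ValueError(f"segment {k}: unknown state {s.state!r}")
        if not (s.end > s.start):
            raise ValueError(f"segment {k}: non-positive length [{s.start}, {s.end})")
        if s.state == INVISIBLE:
            if s.counter is None or s.counter < 1:
                raise ValueError(f"segment {k}: invisible segment needs counter >= 1")
        elif s.counter is not None:
            raise ValueError(f"segment {k}: visible segment must not carry a counter")
        if prev is not None:
            if abs(s.start - prev.end) > tol:
                raise ValueError(
                    f"segment {k}: gap/overlap at {prev.end} -> {s.start}"
                )
            if s.state == prev.state:
                raise ValueError(f"segment {k}: adjacent segments share state {s.state}")
        prev = s


# ---------------------------------------------------------------------------
# coordinate mapping between the concatenated-visible line and the original
# ---------------------------------------------------------------------------


def _visible_index(state: GenomeState):
    """Visible segments plus their cumulative concatenated start offsets."""
    vis = [s for s in state.segments if s.state == VISIBLE]
    cum = [0.0]
    for s in vis:
        cum.append(cum[-1] + s.length)
    return vis, cum  # cum has len(vis)+1 entries; cum[-1] = total visible


def map_concat_to_original(state: GenomeState, x_conc: float) -> float:
    """Map a concatenated-visible coordinate to the original line.

    A point exactly on a junction between visible segments is assigned to
    the visible segment on its right (deterministic tie-break).
    """
    vis, cum = _visible_index(state)
    total = cum[-1]
    if not (0 <= x_conc < total):
        raise ValueError(f"x_conc={x_conc} outside visible extent [0, {total})")
    i = bisect_right(cum, x_conc) - 1
    return vis[i].start + (x_conc - cum[i])


def concat_coordinate(state: GenomeState, x_orig: float) -> float:
    """Inverse of :func:`map_concat_to_original` for visible original points."""
    vis, cum = _visible_index(state)
    for i, s in enumerate(vis):
        if s.start <= x_orig < s.end:
            return cum[i] + (x_orig - s.start)
    raise ValueError(f"original coordinate {x_orig} is not visible")


# ---------------------------------------------------------------------------
# deletion machinery
# ---------------------------------------------------------------------------


def _apply_deletion_batch(
    state: GenomeState, intervals: Sequence[tuple[float, float]]
) -> tuple[GenomeState, list[DeletionEvent]]:
    """Apply sorted, disjoint deletion intervals given in concatenated coords.

    All intervals are interpreted in the concatenated-visible frame of
    ``state`` as it stands on entry, which matches the sweep construction:
    the cursor advances by spacing + length per event, so the intervals of
    one sweep are disjoint and ordered in that single frame.
    """
    vis, cum = _visible_index(state)
    total = cum[-1]

    # Invisible runs keyed by the junction index at which they collapse in
    # concatenated coordinates: run between visible m-1 and m sits at cum[m].
    # Leading/trailing runs sit at junction 0 / len(vis).
    inv_at: dict[int, Segment] = {}
    j = 0
    for s in state.segments:
        if s.state == VISIBLE:
            j += 1
        else:
            inv_at[j] = s

    events: list[DeletionEvent] = []
    new_runs: list[tuple[float, float, int]] = []  # (start, end, counter) original
    swallowed_junctions: set[int] = set()

    for x, e in intervals:
        if not (0 <= x < total):
            raise ValueError(f"deletion point {x} outside visible extent [0, {total})")
        e = min(e, total)
        if e <= x:
            # zero-measure interval (float underflow of a tiny length):
            # no visible mass affected, no event recorded
            continue
        i = bisect_right(cum, x) - 1
        ox = vis[i].start + (x - cum[i])
        jj = bisect_left(cum, e) - 1
        oe = vis[jj].start + (e - cum[jj])
        swallowed = [
            inv_at[m].counter
            for m in range(i + 1, jj + 1)
            if m in inv_at
        ]
        swallowed_junctions.update(
            m for m in range(i + 1, jj + 1) if m in inv_at
        )
        counter = 1 + sum(swallowed)
        new_runs.append((ox, oe, counter))
        events.append(
            DeletionEvent(
                x_conc=x,
                x_orig=ox,
                a=e - x,
                q=len(swallowed),
                swallowed_counters=tuple(swallowed),
            )
        )

    kept = [
        (s.start, s.end, s.counter)
        for m, s in inv_at.items()
        if m not in swallowed_junctions
    ]
    runs = sorted(kept + new_runs)

    # Merge runs that touch (measure-zero in the continuous model, possible
    # after float truncation); counters add because the runs' deletion
    # points end up inside one invisible stretch.
    merged: list[list] = []
    for r in runs:
        if merged and r[0] <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], r[1])
            merged[-1][2] += r[2]
        else:
            merged.append([r[0], r[1], r[2]])

    span_start = state.segments[0].start
    span_end = state.segments[-1].end
    out: list[Segment] = []
    pos = span_start
    for s0, e0, c in merged:
        if s0 > pos:
            out.append(Segment(pos, s0, VISIBLE))
        out.append(Segment(s0, e0, INVISIBLE, c))
        pos = e0
    if span_end > pos:
        out.append(Segment(pos, span_end, VISIBLE))

    new_state = GenomeState(out, state.sweep_index, state.target_visible_length)
    return new_state, events


def apply_deletion(
    state: GenomeState, x_conc: float, a: float
) -> tuple[GenomeState, DeletionEvent]:
    """Delete the concatenated-visible interval ``[x_conc, x_conc + a)``.

    The affected visible mass becomes invisible; invisible runs whose
    deletion point falls inside the interval are merged into the new run,
    whose counter becomes 1 plus the sum of the swallowed counters.  An
    interval overhanging the visible extent is truncated at the edge.
    """
    if not (a > 0):
        raise ValueError(f"deletion length must be positive, got {a}")
    new_state, events = _apply_deletion_batch(state, [(x_conc, x_conc + a)])
    if not events:
        raise ValueError(f"deletion length {a} underflows at x_conc={x_conc}")
    return new_state, events[0]


def run_sweep(
    state: GenomeState, params: SweepParams, rng: np.random.Generator
) -> tuple[GenomeState, list[DeletionEvent]]:
    """Run one full sweep over the concatenated visible genome.

    Spacings (mean ``nu``) and deletion lengths (mean ``mu``) are drawn in
    strict alternation; the cursor advances by spacing + length after each
    event, so the next spacing starts at the end of the previous deletion.
    The sweep stops when the cursor leaves the visible extent; a final
    deletion overhanging the right edge is truncated there (its counter
    still merges any swallowed points).  Increments ``sweep_index``.
    """
    _, cum = _visible_index(state)
    total = cum[-1]
    if total <= 0:
        raise ValueError("state has no visible length left")

    intervals: list[tuple[float, float]] = []
    cursor = 0.0
    while True:
        x = cursor + rng.exponential(params.nu)
        if x >= total:
            break
        a = rng.exponential(params.mu)
        intervals.append((x, min(x + a, total)))
        cursor = x + a
        if cursor >= total:
            break

    new_state, events = _apply_deletion_batch(state, intervals)
    new_state.sweep_index = state.sweep_index + 1
    return new_state, events


def replenish(state: GenomeState, pool: Sequence[GenomeState]) -> GenomeState:
    """Top the visible length back up to ``G`` by copying from replicates.

    Alternating segments (counters preserved verbatim) are appended from
    the donor states, re-based to continue past the recipient's right end.
    The splice starts with visible material: a leading invisible donor
    segment is skipped, and a visible-on-visible junction extends the
    recipient's last visible segment instead of creating an adjacent pair.
    The last copied visible segment is truncated so the total visible
    length hits ``G`` exactly; a trailing invisible segment is not copied.
    """
    G = state.target_visible_length
    need = G - state.visible_length()
    if need <= 1e-9:
        return state.copy()
    if not pool:
        raise ConfigurationError("replenishment needed but the donor pool is empty")
    for donor in pool:
        if donor.sweep_index != state.sweep_index:
            raise ConfigurationError(
                "donor sweep_index differs from recipient "
                f"({donor.sweep_index} != {state.sweep_index})"
            )

    def bulk_rotation(donor: GenomeState) -> list[Segment]:
        # start copying in the donor's stationary bulk, not at its left
        # edge: each sweep restarts its spacing at the origin, so edge
        # segments are systematically shorter and repeatedly copying them
        # would densify the spliced material
        half = donor.visible_length() / 2.0
        acc = 0.0
        k = 0
        for idx, seg in enumerate(donor.segments):
            if seg.state == VISIBLE:
                acc += seg.length
                if acc >= half:
                    k = idx + 1
                    break
        return donor.segments[k:] + donor.segments[:k]

    out = [replace(s) for s in state.segments]
    pos = out[-1].end if out else 0.0
    started = False
    for _ in range(64):  # cyclic passes over the pool
        progressed = False
        for donor in pool:
            for seg in bulk_rotation(donor):
                if not started and seg.state == INVISIBLE:
                    continue
                started = True
                if seg.state == VISIBLE:
                    take = min(seg.length, need)
                    if out and out[-1].state == VISIBLE:
                        out[-1].end += take
                    else:
                        out.append(Segment(pos, pos + take, VISIBLE))
                    pos += take
                    need -= take
                    progressed = True
                    if need <= 1e-9:
                        return GenomeState(out, state.sweep_index, G)
                else:
                    out.append(Segment(pos, pos + seg.length, INVISIBLE, seg.counter))
                    pos += seg.length
        if not progressed:
            break
    raise ConfigurationError(
        f"donor pool exhausted with {need:g} visible length still missing"
    )


@dataclass
class FractionationResult:
    """Trajectory of a multi-replicate fractionation run.

    states[t][r] is replicate ``r`` after sweep ``t`` (post-replenishment
    when enabled); ``states[0]`` holds the fresh genomes.  ``events[t-1][r]``
    lists the deletion events of sweep ``t``.  ``retained[t-1][r]`` is the
    visible fraction surviving sweep ``t`` (visible after the sweep, before
    replenishment, over visible at the sweep start).
    """

    params: SweepParams
    config: SimConfig
    states: list[list[GenomeState]]
    events: list[list[list[DeletionEvent]]]
    retained: list[list[float]] = field(default_factory=list)

    def final_states(self) -> list[GenomeState]:
        return self.states[-1]

    def summary(self) -> list[dict]:
        rows = []
        for t in range(1, len(self.states)):
            for r, st in enumerate(self.states[t]):
                vis = st.visible_segments()
                inv = st.invisible_segments()
                rows.append(
                    {
                        "sweep": t,
                        "replicate": r,
                        "n_visible": len(vis),
                        "n_invisible": len(inv),
                        "mean_visible": float(np.mean([s.length for s in vis]))
                        if vis
                        else float("nan"),
                        "mean_invisible": float(np.mean([s.length for s in inv]))
                        if inv
                        else float("nan"),
                        "retained_fraction": self.retained[t - 1][r],
                        "n_events": len(self.events[t - 1][r]),
                    }
                )
        return rows


def run_fractionation(
    params: SweepParams, config: SimConfig, rng: np.random.Generator | None = None
) -> FractionationResult:
    """Simulate ``config.replicates`` genomes through ``config.sweeps`` sweeps.

    Sweeps use independent RNG substreams per (replicate, sweep), derived
    from ``config.seed``, so trajectories are reproducible and replicates
    are mutually independent.  When replenishment is enabled, each
    replicate is topped up after every sweep from the post-sweep
    (pre-replenishment) snapshot of the next replicate, round-robin; a
    single-replicate run falls back to self-replenishment.
    """
    if config.genome_length < 100 * params.mu:
        warnings.warn(
            "genome_length < 100*mu: edge effects may distort length "
            "distributions",
            stacklevel=2,
        )
    R = config.replicates
    if rng is not None:
        seed_seq = np.random.SeedSequence(int(rng.integers(2**31)))
    else:
        seed_seq = np.random.SeedSequence(config.seed)
    rep_seqs = seed_seq.spawn(R)

    current = [new_genome(config.genome_length) for _ in range(R)]
    states = [[st.copy() for st in current]]
    events: list[list[list[DeletionEvent]]] = []
    retained: list[list[float]] = []

    sweep_rngs = [
        [np.random.default_rng(s) for s in rep_seqs[r].spawn(config.sweeps)]
        for r in range(R)
    ]

    for t in range(1, config.sweeps + 1):
        swept = []
        evts = []
        frac = []
        for r in range(R):
            before = current[r].visible_length()
            st, ev = run_sweep(current[r], params, sweep_rngs[r][t - 1])
            swept.append(st)
            evts.append(ev)
            frac.append(st.visible_length() / before if before > 0 else float("nan"))
        if config.replenish:
            snapshots = [st.copy() for st in swept]
            current = []
            for r in range(R):
                donors = (
                    [snapshots[(r + k) % R] for k in range(1, R)]
                    if R > 1
                    else [snapshots[0]]
                )
                current.append(replenish(swept[r], donors))
        else:
            current = swept
        states.append([st.copy() for st in current])
        events.append(evts)
        retained.append(frac)

    return FractionationResult(params, config, states, events, retained)


# ---------------------------------------------------------------------------
# observables
# ---------------------------------------------------------------------------


def collect_lengths(states: GenomeState | Iterable[GenomeState]) -> LengthSample:
    """Pool visible and invisible segment lengths over one or more genomes."""
    if isinstance(states, GenomeState):
        states = [states]
    states = list(states)
    if not states:
        raise ValueError("no states given")
    idx = {st.sweep_index for st in states}
    if len(idx) != 1:
        raise ValueError(f"states are at different sweep indices: {sorted(idx)}")
    visible = [s.length for st in states for s in st.segments if s.state == VISIBLE]
    invisible = [s.length for st in states for s in st.segments if s.state == INVISIBLE]
    return LengthSample(np.array(visible), np.array(invisible), idx.pop())


def overlap_histogram(events: Iterable[DeletionEvent]) -> dict[int, int]:
    """Empirical frequency table of the overlap count ``q`` of events."""
    counts: dict[int, int] = {}
    for ev in events:
        counts[ev.q] = counts.get(ev.q, 0) + 1
    return dict(sorted(counts.items()))


def counter_census(
    states: GenomeState | Iterable[GenomeState],
) -> dict[int, float]:
    """Empirical distribution of event-counter values over invisible runs.

    Returns proportions summing to 1, or an empty dict when no invisible
    run exists yet (an empty census, distinct from an error).
    """
    if isinstance(states, GenomeState):
        states = [states]
    counts: dict[int, int] = {}
    n = 0
    for st in states:
        for s in st.segments:
            if s.state == INVISIBLE:
                counts[s.counter] = counts.get(s.counter, 0) + 1
                n += 1
    if n == 0:
        return {}
    return {i: c / n for i, c in sorted(counts.items())}
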