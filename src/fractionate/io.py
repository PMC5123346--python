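"""Serialization, run manifests and the seeded fixture generator.

The model lives on an abstract real line, so segment tables are plain TSV
(``start  end  state  counter``) rather than a genomics interval format;
a BED-like integer export is available for visualization only.  Floats
are written with 9 significant digits; counters are exact integers.
"""

from __future__ import annotations

import json
import sys
import time
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from . import __version__
from .errors import ParseError
from .fitting import fit_lengths
from .simulator import (
    INVISIBLE,
    VISIBLE,
    GenomeState,
    LengthSample,
    Segment,
    SimConfig,
    SweepParams,
    collect_lengths,
    run_fractionation,
    validate_genome_state,
)

__all__ = [
    "write_segments",
    "read_segments",
    "write_trajectory_segments",
    "write_lengths",
    "read_lengths",
    "write_bed_like",
    "write_manifest",
    "FIXTURE_SCENARIOS",
    "fixture_generator",
]

_FLOAT_FMT = "{:.9g}"


def _fmt(x: float) -> str:
    return _FLOAT_FMT.format(x)


def write_segments(state: GenomeState, path) -> None:
    """Write one genome's segment table as TSV (counter empty for visible)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("start\tend\tstate\tcounter\n")
        for s in state.segments:
            c = "" if s.counter is None else str(s.counter)
            fh.write(f"{_fmt(s.start)}\t{_fmt(s.end)}\t{s.state}\t{c}\n")


def read_segments(path, sweep_index: int = 0) -> GenomeState:
    """Read a segment table, validating every structural invariant."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty segment file")
    header = lines[0].rstrip("\n").split("\t")
    if header[:4] != ["start", "end", "state", "counter"]:
        raise ParseError(f"{path}: bad header {header!r}", line=1)
    segments: list[Segment] = []
    for ln, raw in enumerate(lines[1:], start=2):
        if not raw.strip():
            continue
        parts = raw.split("\t")
        if len(parts) != 4:
            raise ParseError(f"expected 4 columns, got {len(parts)}", line=ln)
        try:
            start, end = float(parts[0]), float(parts[1])
        except ValueError as exc:
            raise ParseError(str(exc), line=ln) from exc
        state_name = parts[2]
        if state_name not in (VISIBLE, INVISIBLE):
            raise ParseError(f"unknown state {state_name!r}", line=ln)
        counter_txt = parts[3].strip()
        counter = None
        if state_name == INVISIBLE:
            if not counter_txt:
                raise ParseError("invisible row missing counter", line=ln)
            counter = int(counter_txt)
        elif counter_txt:
            raise ParseError("visible row must not carry a counter", line=ln)
        segments.append(Segment(start, end, state_name, counter))
    if not segments:
        raise ParseError(f"{path}: no segment rows")
    gs = GenomeState(
        segments,
        sweep_index=sweep_index,
        target_visible_length=sum(
            s.length for s in segments if s.state == VISIBLE
        ),
    )
    try:
        validate_genome_state(gs)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    return gs


def write_trajectory_segments(states_per_sweep, path) -> None:
    """Write all sweeps of a trajectory to one TSV with sweep/replicate cols."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("sweep\treplicate\tstart\tend\tstate\tcounter\n")
        for t, reps in enumerate(states_per_sweep):
            for r, st in enumerate(reps):
                for s in st.segments:
                    c = "" if s.counter is None else str(s.counter)
                    fh.write(
                        f"{t}\t{r}\t{_fmt(s.start)}\t{_fmt(s.end)}\t{s.state}\t{c}\n"
                    )


def write_lengths(sample: LengthSample, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("length\tstate\n")
        for x in sample.visible:
            fh.write(f"{_fmt(x)}\t{VISIBLE}\n")
        for x in sample.invisible:
            fh.write(f"{_fmt(x)}\t{INVISIBLE}\n")


def read_lengths(path, sweep_index: int = 0) -> LengthSample:
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty length file")
    if lines[0].split("\t")[:2] != ["length", "state"]:
        raise ParseError(f"{path}: bad header", line=1)
    vis, inv = [], []
    for ln, raw in enumerate(lines[1:], start=2):
        if not raw.strip():
            continue
        parts = raw.split("\t")
        if len(parts) != 2:
            raise ParseError(f"expected 2 columns, got {len(parts)}", line=ln)
        try:
            val = float(parts[0])
        except ValueError as exc:
            raise ParseError(str(exc), line=ln) from exc
        if parts[1] == VISIBLE:
            vis.append(val)
        elif parts[1] == INVISIBLE:
            inv.append(val)
        else:
            raise ParseError(f"unknown state {parts[1]!r}", line=ln)
    return LengthSample(np.array(vis), np.array(inv), sweep_index)


def write_bed_like(state: GenomeState, path, name: str = "genome") -> None:
    """Integer-rounded, 0-based half-open export for genome browsers.

    Coordinates here are abstract reals; this rounding is for eyeballing
    only and is not read back by the package.
    """
    path = Path(path)
    with path.open("w") as fh:
        for s in state.segments:
            fh.write(
                f"{name}\t{int(round(s.start))}\t{int(round(s.end))}\t{s.state}\n"
            )


def write_manifest(path, command: str, parameters: dict, seed: int | None) -> dict:
    """Write a JSON run manifest and return it."""
    manifest = {
        "command": command,
        "parameters": parameters,
        "seed": seed,
        "software_version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "argv": sys.argv,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return manifest


# ---------------------------------------------------------------------------
# fixture generator
# ---------------------------------------------------------------------------

#: named study configurations used throughout the test suite and examples
FIXTURE_SCENARIOS: dict[str, dict] = {
    "mu1-nu3-t2": {"mu": 1.0, "nu": 3.0, "sweeps": 2},
    "mu1-nu3-t3": {"mu": 1.0, "nu": 3.0, "sweeps": 3},
    "mu1-nu3-t5": {"mu": 1.0, "nu": 3.0, "sweeps": 5},
    "mu6-nu12-t2": {"mu": 6.0, "nu": 12.0, "sweeps": 2},
    "mu5-nu15-t8": {"mu": 5.0, "nu": 15.0, "sweeps": 8},
    # the mu-grid at fixed r = 1/3 and t = 2: mu = 1..10, nu = 3 mu
    "mu-grid-r13": {"grid_mu": list(range(1, 11)), "ratio": 1.0 / 3.0, "sweeps": 2},
}


def fixture_generator(scenario: str, seed: int, outdir) -> dict:
    """Generate deterministic simulator outputs for a named scenario.

    Writes, per configuration: the final-sweep segment tables (one per
    replicate), a pooled length TSV, and a summary JSON with the fitted
    observables.  Returns the summary dict.  Identical (scenario, seed)
    produce byte-identical files.
    """
    if scenario not in FIXTURE_SCENARIOS:
        raise ValueError(
            f"unknown scenario {scenario!r}; available: "
            + ", ".join(sorted(FIXTURE_SCENARIOS))
        )
    spec = FIXTURE_SCENARIOS[scenario]
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def one_run(mu, nu, sweeps, tag, run_seed):
        params = SweepParams(nu=nu, mu=mu)
        config = SimConfig(sweeps=sweeps, replicates=5, seed=run_seed)
        result = run_fractionation(params, config)
        finals = result.final_states()
        for r, st in enumerate(finals):
            write_segments(st, outdir / f"{tag}.rep{r}.segments.tsv")
        sample = collect_lengths(finals)
        write_lengths(sample, outdir / f"{tag}.lengths.tsv")
        fit = fit_lengths(sample)
        return {
            "mu": mu,
            "nu": nu,
            "sweeps": sweeps,
            "seed": run_seed,
            "lambda_inv": fit.lambda_inv,
            "alpha": fit.alpha,
            "beta": fit.beta,
            "n_visible": fit.n_visible,
            "n_invisible": fit.n_invisible,
        }

    summary: dict = {"scenario": scenario, "seed": seed, "runs": []}
    if "grid_mu" in spec:
        for k, mu in enumerate(spec["grid_mu"]):
            nu = mu / spec["ratio"]
            summary["runs"].append(
                one_run(mu, nu, spec["sweeps"], f"{scenario}.mu{mu}", seed + k)
            )
    else:
        summary["runs"].append(
            one_run(spec["mu"], spec["nu"], spec["sweeps"], scenario, seed)
        )
    (outdir / f"{scenario}.summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    return summary
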