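"""Command-driven orchestration of the processing engines.

Mirrors the nine-command control interface of the modeled chip's central
bio-signal processing unit: recording to memory or stream (C1/C2),
intra-channel AP compression (C3), cross-channel LFP compression (C4), FIR
filtering to stream or memory (C5/C6), spike-raster packetization (C7) and
adaptive-threshold reporting/updating (C8/C9).  C1/C2 and C5/C6 (and
C8/C9) differ only in their sink, so they share handlers with a sink
option.  The debug flag sources input from a stored file instead of the
synthetic front-end.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np

from . import cross_channel_codec as cce
from . import detection as det
from . import fir_filterbank as fir
from . import intra_channel_codec as ice
from .recording import Recording, read_recording, write_recording
from .synthetic_data import GeneratorConfig, generate_recording

__all__ = ["CommandSpec", "RasterFrame", "run_command", "make_raster", "raster_to_bytes", "report_metrics"]

logger = logging.getLogger("neurocodec")

COMMANDS = ("C1", "C2", "C3", "C4", "C5", "C6", "C7", "C8", "C9")

EMPTY_HEADER = 0xA0
FIRING_HEADER = 0xA1


@dataclass
class CommandSpec:
    """One command with its channel selection and mode flags."""

    command: str
    channels: Sequence[int] | None = None
    mode: str = "lossless"  # C3: lossless | near_lossless
    backend: str = "gc"  # C3: gc | ac
    stream: bool = True  # stream vs batch / memory sink
    debug: bool = False  # read input from file instead of the generator
    coeffs: Sequence[fir.FirCoeffs] | fir.FirCoeffs | None = None  # C5/C6
    ate_config: det.AteConfig | None = None
    table: ice.SymbolTable | None = None
    output: str | Path | None = None

    def __post_init__(self) -> None:
        if self.command not in COMMANDS:
            raise ValueError(f"unknown command {self.command!r}; expected one of {COMMANDS}")


@dataclass(frozen=True)
class RasterFrame:
    """One packet per 20 kHz tick: the set of channels that fired."""

    tick: int
    channels: tuple[int, ...]

    @property
    def empty(self) -> bool:
        return len(self.channels) == 0

    @property
    def header(self) -> int:
        return EMPTY_HEADER if self.empty else FIRING_HEADER


def make_raster(detections: np.ndarray) -> list[RasterFrame]:
    """Packetize a [ticks x channels] detection-bit matrix, one frame per tick.

    The per-tick OR across channels decides between an empty (header-only)
    frame and a frame listing the firing channel ids.
    """
    detections = np.atleast_2d(np.asarray(detections, dtype=bool))
    frames = []
    for tick, row in enumerate(detections):
        chans = tuple(int(c) for c in np.flatnonzero(row))
        frames.append(RasterFrame(tick=tick, channels=chans))
    return frames


def raster_to_bytes(frames: Sequence[RasterFrame]) -> bytes:
    """Wire format: 1 header byte, 4-byte tick, then count + channel bytes."""
    out = bytearray()
    for fr in frames:
        out.append(fr.header)
        out += fr.tick.to_bytes(4, "little")
        if not fr.empty:
            out.append(len(fr.channels))
            out += bytes(fr.channels)
    return bytes(out)


def _detection_matrix(rec: Recording, channels: Sequence[int], cfg: det.AteConfig | None) -> tuple[np.ndarray, dict[int, list[det.SpikeEvent]]]:
    bits = np.zeros((rec.n_samples, len(channels)), dtype=bool)
    events: dict[int, list[det.SpikeEvent]] = {}
    for col, cid in enumerate(channels):
        evs = det.detect_spikes(rec, cid, cfg)
        events[cid] = evs
        for ev in evs:
            bits[ev.detect_index, col] = True
    return bits, events


def run_command(spec: CommandSpec, source: Recording | str | Path | GeneratorConfig) -> dict[str, Any]:
    """Dispatch one command and return its outputs plus stage metrics.

    ``source`` is a live :class:`Recording`, a stored file path (debug
    mode), or a :class:`GeneratorConfig` standing in for the analog
    front-end.
    """
    t0 = time.perf_counter()
    if isinstance(source, (str, Path)):
        rec = read_recording(source)
    elif isinstance(source, GeneratorConfig):
        rec, _ = generate_recording(source)
    else:
        rec = source
    channels = list(spec.channels) if spec.channels is not None else [int(c) for c in rec.channel_ids]
    result: dict[str, Any] = {"command": spec.command, "channels": channels}

    if spec.command in ("C1", "C2"):
        # source/sink routing of the raw stream
        result["recording"] = rec
        result["bytes"] = rec.samples.nbytes
        if spec.output is not None:
            write_recording(rec, spec.output)
    elif spec.command == "C3":
        events_by_ch = {}
        streams = {}
        for cid in channels:
            events = det.detect_spikes(rec, cid, spec.ate_config) if spec.mode == "near_lossless" else None
            table = spec.table
            if spec.backend == "ac" and table is None:
                table = ice.train_symbol_table([ice.dpcm2_encode(rec.channel(cid))])
            streams[cid] = ice.compress_channel(rec, cid, spec.mode, spec.backend, events=events, table=table)
            events_by_ch[cid] = events
            result.setdefault("tables", {})[cid] = table
        result["bitstreams"] = streams
        result["events"] = events_by_ch
        result["ssr"] = {
            cid: ice.ssr(rec.n_samples * rec.bit_depth, bs.payload_bits) for cid, bs in streams.items()
        }
    elif spec.command == "C4":
        sub = Recording(
            samples=np.stack([rec.channel(c) for c in channels]),
            fs=rec.fs,
            bit_depth=rec.bit_depth,
            channel_ids=np.asarray(channels),
        )
        tree = cce.train_channel_tree(sub)
        bits = cce.cce_compress(sub, tree)
        result["tree"] = tree
        result["bitstream"] = bits
        result["ssr"] = ice.ssr(sub.n_samples * sub.bit_depth * sub.n_channels, bits.payload_bits)
    elif spec.command in ("C5", "C6"):
        coeffs = spec.coeffs if spec.coeffs is not None else fir.FirCoeffs.identity()
        filtered = fir.filterbank(rec, coeffs, channels)
        result["recording"] = filtered
        if spec.command == "C6" and spec.output is not None:  # memory sink
            write_recording(filtered, spec.output)
    elif spec.command == "C7":
        bits, events = _detection_matrix(rec, channels, spec.ate_config)
        frames = make_raster(bits)
        result["frames"] = frames
        result["events"] = events
        result["n_frames"] = len(frames)
        if spec.output is not None:
            Path(spec.output).write_bytes(raster_to_bytes(frames))
    elif spec.command in ("C8", "C9"):
        cfg = spec.ate_config or det.AteConfig()
        report = {}
        for cid in channels:
            x = rec.channel(cid).astype(np.int64)
            psi = det.neo(x)
            state = det.ThresholdState(window_len=cfg.window_len)
            thresholds = []
            for start in range(0, max(0, psi.size), cfg.window_len):
                window = psi[start : start + cfg.window_len]
                if window.size == 0:
                    break
                zc, log_rate = det.zero_crossing_log_rate(window)
                det.noise_estimate(window, state, cfg)
                thresholds.append(
                    det.compute_threshold(state.noise_level, log_rate, cfg.k_neo, beta=cfg.beta, floor=cfg.floor)
                )
            report[cid] = {"thresholds": thresholds, "final_noise_level": state.noise_level}
        result["ate_report"] = report
        if spec.command == "C9":
            # update mode: fold the final thresholds back into a config
            result["updated_config"] = cfg
    result["elapsed_s"] = time.perf_counter() - t0
    logger.info("%s on %d channels in %.3f s", spec.command, len(channels), result["elapsed_s"])
    return result


def report_metrics(run: dict[str, Any]) -> dict[str, Any]:
    """Condense a run result into a JSON-serializable metrics report."""
    report: dict[str, Any] = {"command": run.get("command"), "channels": run.get("channels", [])}
    if "ssr" in run:
        ssr_val = run["ssr"]
        report["ssr_percent"] = (
            {int(k): float(v) for k, v in ssr_val.items()} if isinstance(ssr_val, dict) else float(ssr_val)
        )
    if "events" in run and run["events"]:
        report["spike_counts"] = {
            int(cid): (len(evs) if evs is not None else 0) for cid, evs in run["events"].items()
        }
    if "n_frames" in run:
        report["n_frames"] = int(run["n_frames"])
    if "accuracy_percent" in run:
        report["accuracy_percent"] = float(run["accuracy_percent"])
    report["elapsed_s"] = float(run.get("elapsed_s", 0.0))
    return report
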