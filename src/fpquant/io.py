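"""Readers and writers for the pipeline's file formats.

Spectra, traces and tables travel as headered CSV; image stacks as
multi-page TIFF in TZCYX page order (time outermost); ground truth as a
JSON sidecar next to whichever file it describes.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .photobleach import BleachTrace
from .simulate import GroundTruth
from .spectra import Spectrum

__all__ = [
    "write_spectrum_csv",
    "read_spectrum_csv",
    "write_trace_csv",
    "read_trace_csv",
    "write_stack_tiff",
    "read_stack_tiff",
    "write_ground_truth",
    "read_ground_truth",
]


def write_spectrum_csv(spectrum: Spectrum, path: str | Path) -> None:
    pd.DataFrame(
        {"wavelength_nm": spectrum.wavelength, "intensity": spectrum.intensity}
    ).to_csv(path, index=False)


def read_spectrum_csv(path: str | Path, kind: str = "emission") -> Spectrum:
    df = pd.read_csv(path)
    return Spectrum(df["wavelength_nm"].to_numpy(), df["intensity"].to_numpy(), kind=kind)


def write_trace_csv(trace: BleachTrace, path: str | Path) -> None:
    pd.DataFrame({"time_s": trace.time, "intensity": trace.intensity}).to_csv(path, index=False)


def read_trace_csv(path: str | Path, **metadata) -> BleachTrace:
    df = pd.read_csv(path)
    return BleachTrace(df["time_s"].to_numpy(), df["intensity"].to_numpy(), **metadata)


def write_stack_tiff(stack: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(
        path, np.asarray(stack, dtype=np.float32), photometric="minisblack"
    )


def read_stack_tiff(path: str | Path) -> np.ndarray:
    return tifffile.imread(path).astype(float)


def write_ground_truth(gt: GroundTruth, path: str | Path) -> None:
    Path(path).write_text(json.dumps(gt.to_dict(), indent=2) + "\n")


def read_ground_truth(path: str | Path) -> GroundTruth:
    return GroundTruth(**json.loads(Path(path).read_text()))
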