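"""Reading and writing delimited signal text and JSON model files.

Signals travel as plain delimited numeric text (the UCI physical-action
dialect: one row per sample, one column per muscle channel, no header).
Trained network models are serialized to a versioned JSON schema so that a
model trained in one process predicts identically after a reload elsewhere.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

MODEL_FORMAT_VERSION = "emg-gmdh-model-1"


class SignalParseError(ValueError):
    """Raised when a signal text file does not parse as a numeric matrix."""


class ModelFormatError(ValueError):
    """Raised when a model file is truncated, malformed or wrong-versioned."""


@dataclass
class SignalFrame:
    """A multichannel signal: rows are time samples, columns are channels.

    Attributes
    ----------
    data : ndarray of shape (n_samples, n_channels)
        Amplitude values in arbitrary sensor units.
    channel_names : list of str
        Ordered channel labels; defaults to ``ch1..chN``.
    sample_index_origin : int
        Index of the first row (0 by convention).
    """

    data: np.ndarray
    channel_names: list[str] = field(default_factory=list)
    sample_index_origin: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("SignalFrame data must be 2-D (samples x channels)")
        if self.data.shape[1] < 1:
            raise ValueError("SignalFrame needs at least one channel")
        if self.data.size and not np.all(np.isfinite(self.data)):
            raise ValueError("SignalFrame data must be finite")
        if not self.channel_names:
            self.channel_names = [f"ch{i + 1}" for i in range(self.data.shape[1])]
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError("channel_names length must match channel count")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def channel(self, key: int | str) -> np.ndarray:
        """Return one channel as a 1-D array, by index or by name."""
        if isinstance(key, str):
            key = self.channel_names.index(key)
        return self.data[:, key]


def _split_line(line: str, delimiter: str) -> list[str]:
    if delimiter == "tab":
        return line.split("\t")
    if delimiter == "comma":
        return line.split(",")
    # auto: a single comma or any run of whitespace separates fields
    if "," in line:
        return [tok.strip() for tok in line.split(",")]
    return line.split()


def read_signal_text(path: str | os.PathLike, delimiter: str = "auto") -> SignalFrame:
    """Read a headerless delimited numeric matrix into a :class:`SignalFrame`.

    ``delimiter`` is one of ``auto`` (whitespace runs or single commas),
    ``tab`` or ``comma``.  Rows must all carry the same number of numeric
    fields; ragged or non-numeric input raises :class:`SignalParseError`
    naming the offending line.
    """
    if delimiter not in ("auto", "tab", "comma"):
        raise ValueError(f"unknown delimiter mode: {delimiter!r}")
    rows: list[list[float]] = []
    width = None
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            tokens = _split_line(line, delimiter)
            try:
                values = [float(tok) for tok in tokens]
            except ValueError as exc:
                raise SignalParseError(
                    f"{path}: line {lineno}: non-numeric token ({exc})"
                ) from None
            if width is None:
                width = len(values)
            elif len(values) != width:
                raise SignalParseError(
                    f"{path}: line {lineno}: expected {width} fields, got {len(values)}"
                )
            rows.append(values)
    if not rows:
        raise SignalParseError(f"{path}: empty signal file")
    return SignalFrame(np.array(rows, dtype=float))


def write_signal_text(frame: SignalFrame, path: str | os.PathLike) -> None:
    """Write a frame as tab-delimited text, 6 decimals, no header."""
    with open(path, "w", encoding="utf-8") as fh:
        for row in frame.data:
            fh.write("\t".join(f"{v:.6f}" for v in row) + "\n")


def save_model(model, path: str | os.PathLike) -> None:
    """Serialize a trained :class:`~emg_gmdh.gmdh_core.GmdhModel` to JSON."""
    payload = {"format": MODEL_FORMAT_VERSION, "model": model.to_dict()}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)


def load_model(path: str | os.PathLike):
    """Load a model saved by :func:`save_model`; wrong schema raises."""
    from .gmdh_core import GmdhModel

    try:
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ModelFormatError(f"{path}: not valid model JSON ({exc})") from None
    if not isinstance(payload, dict) or "format" not in payload:
        raise ModelFormatError(f"{path}: missing format version tag")
    if payload["format"] != MODEL_FORMAT_VERSION:
        raise ModelFormatError(
            f"{path}: unsupported model format {payload['format']!r}"
        )
    try:
        return GmdhModel.from_dict(payload["model"])
    except (KeyError, TypeError) as exc:
        raise ModelFormatError(f"{path}: malformed model payload ({exc})") from None
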