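"""Amplitude-envelope extraction.

The reconstruction target of the backward decoding model is the slowly
varying amplitude of the speech waveform: the block root-mean-square of the
audio, compressed with a power law (exponent 0.3, approximating perceived
loudness), sampled at the working rate of the preprocessed EEG (64 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AudioStream", "Envelope", "extract_envelope", "normalize_peak"]


@dataclass
class AudioStream:
    """A mono waveform with its sampling rate.

    Samples are floats, nominally in [-1, 1] when read from disk; raw
    stimuli and behind-the-ear microphone mixes are both represented this
    way.
    """

    samples: np.ndarray
    fs: float
    source_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("AudioStream expects a 1-D sample array")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs


@dataclass
class Envelope:
    """Nonnegative compressed-amplitude series at the working rate."""

    samples: np.ndarray
    fs: float = 64.0
    source_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("Envelope expects a 1-D sample array")
        if self.samples.size and self.samples.min() < 0:
            raise ValueError("envelope samples must be nonnegative")

    def __len__(self) -> int:
        return self.samples.size


def extract_envelope(
    audio: AudioStream,
    target_fs: float = 64.0,
    power: float = 0.3,
    window_blocks: int = 1,
) -> Envelope:
    """Compute the compressed block-RMS envelope of an audio stream.

    Output sample ``n`` is the RMS of the block of
    ``floor(fs_audio / target_fs) * window_blocks`` audio samples starting
    at the n-th block boundary, raised to ``power``.  The output length is
    ``floor(duration * target_fs)``.  For non-integer rate ratios, block
    boundaries are truncated to the nearest audio sample, so the boundary
    error is below one audio sample per block.

    Parameters
    ----------
    audio : AudioStream
        Input waveform.
    target_fs : float
        Output rate in Hz; must not exceed the audio rate.  Default 64, the
        working rate of the preprocessed EEG.
    power : float
        Compressive exponent applied to the block RMS.  Default 0.3.
    window_blocks : int
        RMS window length in units of one output block.  Default 1.
    """
    if target_fs > audio.fs:
        raise ValueError(
            f"target_fs ({target_fs} Hz) exceeds the audio rate ({audio.fs} Hz)"
        )
    if power <= 0:
        raise ValueError("power must be positive")
    if window_blocks < 1:
        raise ValueError("window_blocks must be >= 1")

    x = audio.samples
    hop = audio.fs / target_fs
    block = int(np.floor(hop)) * int(window_blocks)
    if x.size < block:
        raise ValueError(
            f"audio ({x.size} samples) is shorter than one block ({block} samples)"
        )
    n_out = int(np.floor(x.size / audio.fs * target_fs))
    # clip trailing blocks that would run past the signal (window_blocks > 1)
    starts = np.floor(np.arange(n_out) * hop).astype(np.intp)
    n_out = int(np.searchsorted(starts, x.size - block, side="right"))
    starts = starts[:n_out]

    if float(hop).is_integer() and window_blocks == 1:
        seg = x[: n_out * block].reshape(n_out, block)
    else:
        seg = x[starts[:, None] + np.arange(block)[None, :]]
    rms = np.sqrt(np.mean(seg * seg, axis=1))
    return Envelope(rms**power, fs=target_fs, source_id=audio.source_id)


def normalize_peak(audio: AudioStream, peak_db: float = -1.0) -> AudioStream:
    """Scale a waveform so its absolute peak sits at ``peak_db`` dBFS.

    Stimulus-preparation helper (peak normalization makes narratives
    comparable in level); it is not part of envelope extraction itself.
    """
    peak = np.max(np.abs(audio.samples))
    if peak == 0:
        raise ValueError("cannot peak-normalize an all-zero waveform")
    target = 10.0 ** (peak_db / 20.0)
    return AudioStream(audio.samples * (target / peak), audio.fs, audio.source_id)
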