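"""Small analysis helpers for simulation output."""

from __future__ import annotations

import numpy as np

__all__ = [
    "rmse",
    "cosine_similarity_trace",
    "dominant_frequency",
    "lowpass_filter",
    "settling_time",
]


def rmse(a, b) -> float:
    """Root mean squared elementwise difference between two arrays."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def cosine_similarity_trace(decoded: np.ndarray, target) -> np.ndarray:
    """Per-timestep cosine similarity between decoded rows and a fixed target.

    Returns 0 for rows where either vector has zero norm.
    """
    decoded = np.atleast_2d(np.asarray(decoded, dtype=float))
    target = np.asarray(target, dtype=float)
    if decoded.shape[1] != target.size:
        raise ValueError(
            f"decoded has {decoded.shape[1]} columns, target has {target.size}"
        )
    tnorm = np.linalg.norm(target)
    norms = np.linalg.norm(decoded, axis=1)
    denom = norms * tnorm
    sims = np.zeros(decoded.shape[0])
    ok = denom > 0
    sims[ok] = (decoded[ok] @ target) / denom[ok]
    return sims


def dominant_frequency(signal, dt: float, pad_factor: int = 8) -> float:
    """Location (Hz) of the periodogram's peak, excluding the DC component.

    The signal is mean-subtracted and zero-padded by ``pad_factor`` before
    the FFT so the peak location resolves finer than the raw bin width
    1/duration.
    """
    x = np.asarray(signal, dtype=float).ravel()
    if x.size < 4:
        raise ValueError("signal too short for a frequency estimate")
    x = x - x.mean()
    nfft = int(2 ** np.ceil(np.log2(max(pad_factor, 1) * x.size)))
    spectrum = np.abs(np.fft.rfft(x, n=nfft))
    freqs = np.fft.rfftfreq(nfft, dt)
    spectrum[0] = 0.0
    return float(freqs[np.argmax(spectrum)])


def lowpass_filter(x, dt: float, tau) -> np.ndarray:
    """Causal first-order lowpass of a sampled signal (state starts at 0).

    Matches the simulator's synaptic/probe filtering exactly:
    ``y[t] = y[t-1] * exp(-dt/tau) + x[t] * (1 - exp(-dt/tau))``.
    """
    x = np.asarray(x, dtype=float)
    if not tau:
        return x.copy()
    decay = np.exp(-dt / tau)
    y = np.zeros_like(x)
    prev = np.zeros(x.shape[1:] if x.ndim > 1 else ())
    for i in range(x.shape[0]):
        prev = prev * decay + x[i] * (1.0 - decay)
        y[i] = prev
    return y


def settling_time(times, similarity, threshold: float = 0.8) -> float:
    """First time after which ``similarity`` stays above ``threshold``.

    Returns ``inf`` if the trace never settles above the threshold.
    """
    times = np.asarray(times, dtype=float)
    similarity = np.asarray(similarity, dtype=float)
    if times.shape != similarity.shape:
        raise ValueError("times and similarity must have equal length")
    below = np.where(similarity <= threshold)[0]
    if below.size == 0:
        return float(times[0])
    last = below[-1]
    if last == len(times) - 1:
        return float("inf")
    return float(times[last + 1])
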