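"""Background (interictal) scalp-EEG model.

The background is the sum of three seeded components per channel:

* broadband 1/f^alpha noise (alpha = 1), the dominant "pink" spectral
  envelope of resting EEG, scaled to a physiologic RMS of a few tens of uV;
* a posterior-dominant alpha rhythm (8-12 Hz) with a slow waxing-waning
  envelope, strongest over O1/O2 and fading toward frontal leads;
* white sensor noise of a couple of uV RMS.

This is a minimal model reproducing the band structure clinicians read,
not a biophysical forward model.
"""

from __future__ import annotations

import numpy as np

from weakeeg.records import ELECTRODE_XY, MONTAGE_1020, N_CHANNELS, EEGRecord

#: Posterior-gradient gain of the alpha rhythm per electrode: 1.0 at the
#: occiput, fading toward the front.
_ALPHA_GAIN = {
    name: 0.15 + 0.85 * max(0.0, -ELECTRODE_XY[name][1]) for name in MONTAGE_1020
}
_ALPHA_GAIN["O1"] = _ALPHA_GAIN["O2"] = 1.0


def _pink_noise(n: int, n_ch: int, rng: np.random.Generator, alpha: float = 1.0) -> np.ndarray:
    """1/f^alpha noise via spectral shaping of white Gaussian noise, unit RMS.

    Runs in single precision (scipy.fft preserves float32), which is ample
    for a noise generator and halves the cost of long records.
    """
    from scipy import fft as sfft

    white = rng.standard_normal((n, n_ch)).astype(np.float32)
    spec = sfft.rfft(white, axis=0)
    freqs = np.fft.rfftfreq(n, d=1.0)
    scale = np.ones_like(freqs, dtype=np.float32)
    nz = freqs > 0
    scale[nz] = freqs[nz].astype(np.float32) ** np.float32(-alpha / 2.0)
    scale[0] = 0.0  # no DC
    shaped = sfft.irfft(spec * scale[:, None], n=n, axis=0)
    shaped /= shaped.std(axis=0, keepdims=True)
    return shaped


def generate_background(
    duration_s: float,
    fs: float = 200.0,
    seed: int = 0,
    rhythm_profile: dict | None = None,
    record_id: str = "synthetic",
) -> EEGRecord:
    """Generate a seeded 19-channel background record with no gold events.

    Parameters
    ----------
    duration_s, fs
        Record length in seconds and sampling rate in Hz; both must be > 0.
    seed
        Seeds every random component; identical calls are bit-identical.
    rhythm_profile
        Optional overrides: ``alpha_freq_hz`` (default drawn in 8-12),
        ``alpha_amp_uv`` (occipital alpha amplitude, default ~20),
        ``broadband_rms_uv`` (pink-noise RMS, default 15),
        ``sensor_noise_uv`` (default 2).
    """
    if duration_s <= 0:
        raise ValueError(f"duration_s must be positive, got {duration_s}")
    if fs <= 0:
        raise ValueError(f"fs must be positive, got {fs}")
    profile = dict(rhythm_profile or {})
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs

    broadband_rms = float(profile.get("broadband_rms_uv", 15.0))
    sensor_rms = float(profile.get("sensor_noise_uv", 2.0))
    alpha_amp = float(profile.get("alpha_amp_uv", 20.0))
    alpha_freq = float(profile.get("alpha_freq_hz", rng.uniform(8.0, 12.0)))

    data = broadband_rms * _pink_noise(n, N_CHANNELS, rng)

    # Posterior alpha with a slow (~0.3 Hz lowpass noise) waxing-waning
    # envelope shared across channels, plus small per-channel phase offsets.
    env = _pink_noise(n, 1, rng, alpha=2.0)[:, 0]
    env = 0.6 + 0.4 * (env - env.min()) / max(np.ptp(env), 1e-12)
    phases = rng.uniform(0, 2 * np.pi, N_CHANNELS)
    gains = np.array([_ALPHA_GAIN[name] for name in MONTAGE_1020])
    alpha_wave = np.sin(2 * np.pi * alpha_freq * t[:, None] + phases[None, :])
    data += alpha_amp * env[:, None] * gains[None, :] * alpha_wave

    data += sensor_rms * rng.standard_normal((n, N_CHANNELS))

    return EEGRecord(record_id=record_id, fs=fs, data=data.astype(np.float32))
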