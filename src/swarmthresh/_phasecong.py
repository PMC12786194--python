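"""2-D phase congruency via a log-Gabor filter bank.

Phase congruency marks image locations where Fourier components are
maximally in phase (edges, lines), independent of local contrast.  The
implementation follows the widely used frequency-domain construction: a
bank of log-Gabor filters (``nscale`` radial scales x ``norient``
orientations) is applied in the Fourier domain; per orientation, local
energy is the magnitude of the summed analytic responses, compensated by
an estimated noise threshold and by a frequency-spread weighting, and the
per-orientation energies are normalized by the total response amplitude.

Used as the weighting/feature map inside the feature-similarity metric.
"""

from __future__ import annotations

import numpy as np

__all__ = ["phase_congruency"]


def _lowpass(shape: tuple[int, int], cutoff: float = 0.45, order: int = 15) -> np.ndarray:
    rows, cols = shape
    fy = np.fft.fftfreq(rows)[:, None]
    fx = np.fft.fftfreq(cols)[None, :]
    radius = np.sqrt(fx * fx + fy * fy)
    return 1.0 / (1.0 + (radius / cutoff) ** (2 * order))


def phase_congruency(
    image: np.ndarray,
    nscale: int = 4,
    norient: int = 4,
    min_wavelength: float = 6.0,
    mult: float = 2.0,
    sigma_onf: float = 0.55,
    d_theta_sigma: float = 1.2,
    k_noise: float = 2.0,
    cut_off: float = 0.5,
    g: float = 10.0,
    eps: float = 1e-4,
) -> np.ndarray:
    """Compute the phase-congruency map of a 2-D image (values in [0, 1])."""
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D image")
    rows, cols = img.shape
    imfft = np.fft.fft2(img)

    fy = np.fft.fftfreq(rows)[:, None]
    fx = np.fft.fftfreq(cols)[None, :]
    radius = np.sqrt(fx * fx + fy * fy)
    radius[0, 0] = 1.0  # avoid log(0) at DC; DC gain forced to 0 below
    theta = np.arctan2(-fy, fx)
    sin_t, cos_t = np.sin(theta), np.cos(theta)
    lp = _lowpass((rows, cols))

    # radial log-Gabor components, one per scale
    radial = []
    for s in range(nscale):
        f0 = 1.0 / (min_wavelength * mult**s)
        lg = np.exp(-(np.log(radius / f0) ** 2) / (2.0 * np.log(sigma_onf) ** 2))
        lg *= lp
        lg[0, 0] = 0.0
        radial.append(lg)

    theta_sigma = np.pi / norient / d_theta_sigma
    pc_numerator = np.zeros((rows, cols))
    total_sum_an = np.zeros((rows, cols))

    for o in range(norient):
        angle = o * np.pi / norient
        # angular spread around the filter orientation
        ds = sin_t * np.cos(angle) - cos_t * np.sin(angle)
        dc = cos_t * np.cos(angle) + sin_t * np.sin(angle)
        dtheta = np.abs(np.arctan2(ds, dc))
        spread = np.exp(-(dtheta**2) / (2.0 * theta_sigma**2))

        sum_e = np.zeros((rows, cols))
        sum_o = np.zeros((rows, cols))
        sum_an = np.zeros((rows, cols))
        max_an = np.zeros((rows, cols))
        responses = []
        tau = 0.0
        for s in range(nscale):
            resp = np.fft.ifft2(imfft * radial[s] * spread)
            e, od = resp.real, resp.imag
            an = np.abs(resp)
            responses.append((e, od))
            sum_e += e
            sum_o += od
            sum_an += an
            max_an = np.maximum(max_an, an)
            if s == 0:
                # Rayleigh-based noise estimate from the smallest-scale response
                tau = np.median(an) / np.sqrt(np.log(4.0))

        x_energy = np.sqrt(sum_e**2 + sum_o**2) + eps
        mean_e, mean_o = sum_e / x_energy, sum_o / x_energy
        energy = np.zeros((rows, cols))
        for e, od in responses:
            energy += e * mean_e + od * mean_o - np.abs(e * mean_o - od * mean_e)

        # total noise amplitude across scales (geometric falloff 1/mult)
        total_tau = tau * (1.0 - (1.0 / mult) ** nscale) / (1.0 - 1.0 / mult)
        noise_mean = total_tau * np.sqrt(np.pi / 2.0)
        noise_sigma = total_tau * np.sqrt((4.0 - np.pi) / 2.0)
        T = noise_mean + k_noise * noise_sigma
        energy = np.maximum(energy - T, 0.0)

        # down-weight locations responding at only a narrow frequency range
        width = (sum_an / (max_an + eps)) / nscale
        weight = 1.0 / (1.0 + np.exp(g * (cut_off - width)))

        pc_numerator += weight * energy
        total_sum_an += sum_an

    return pc_numerator / (total_sum_an + eps)
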