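"""Phase-conjugation focusing and its non-invasive validation.

Displaying the conjugate phases of a field-TM row makes all SLM segments
interfere constructively at the corresponding emitter: with ``n_slm``
phase-only segments and a circular-Gaussian row the expected intensity
enhancement over random illumination is ``1 + (pi/4)(n_slm - 1)``.

Two validation paths are kept strictly separate:

* *control side* (invasive, available only in simulation or with a camera
  behind the sample): the excitation intensity is evaluated at every emitter
  and at background probe positions; the focus SNR is the intensity at the
  target divided by the mean off-target intensity.  A peak-over-std variant
  is logged alongside since both conventions are in circulation.
* *epi side* (non-invasive): when light is focused on a single emitter, the
  epi-detected fluorescence frame is dominated by one eigen-pattern and its
  spatial contrast rises toward the single-speckle value — for an N-emitter
  object the contrast-squared (normalized variance) gain approaches N/2.
  A candidate pattern is declared a focus when the normalized variance of
  its (high-passed) epi frame exceeds ``theta_focus`` times the median under
  random illumination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .factorize import high_pass_image
from .optics_sim import FieldTM, substream

__all__ = [
    "FocusRecord",
    "conjugate_focus_pattern",
    "evaluate_focus",
    "epi_variance_validation",
]


@dataclass
class FocusRecord:
    """Control-side metrics for one candidate focus pattern."""

    target_index: int
    phases: np.ndarray
    emitter_intensity: np.ndarray
    probe_intensity: np.ndarray
    snr: float
    snr_std: float
    enhancement: float
    selective: bool
    epi_variance_score: float = np.nan
    verdict: str = "unknown"


def conjugate_focus_pattern(t_row: np.ndarray) -> np.ndarray:
    """Phase-only conjugate of a field-TM row: phases = -arg(t), in [0, 2*pi)."""
    t_row = np.asarray(t_row)
    if np.all(t_row == 0):
        raise ValueError("cannot conjugate an all-zero row")
    return (-np.angle(t_row)) % (2.0 * np.pi)


def _intensities(field_tm: FieldTM, phases: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    e = np.exp(1j * np.asarray(phases))
    at_emitters = np.abs(field_tm.matrix @ e) ** 2
    at_probes = (
        np.abs(field_tm.probe_matrix @ e) ** 2
        if field_tm.probe_matrix is not None
        else np.zeros(0)
    )
    return at_emitters, at_probes


def evaluate_focus(
    field_tm: FieldTM,
    phases: np.ndarray,
    target_index: int,
    n_random: int = 200,
    seed: int = 0,
) -> FocusRecord:
    """Score a candidate pattern against the ground-truth field TM (control side).

    ``snr`` is the excitation intensity at the target over the mean intensity
    at the other emitters and background probe grains; ``snr_std`` is the
    peak-minus-background over the background standard deviation.
    ``enhancement`` compares the target intensity with its mean under
    ``n_random`` random phase patterns.
    """
    if not 0 <= target_index < field_tm.n_targets:
        raise IndexError(f"target_index {target_index} out of range")
    at_emitters, at_probes = _intensities(field_tm, phases)
    background = np.concatenate(
        [np.delete(at_emitters, target_index), at_probes]
    )
    peak = float(at_emitters[target_index])
    if background.size == 0:
        raise ValueError("no off-target emitters or probes to estimate background")
    snr = peak / max(background.mean(), np.finfo(float).tiny)
    snr_std = (peak - background.mean()) / max(background.std(), np.finfo(float).tiny)
    rng = substream(seed, "focus_random_baseline")
    rand_phases = rng.uniform(0.0, 2.0 * np.pi, size=(field_tm.n_slm, n_random))
    rand_i = np.abs(field_tm.matrix[target_index] @ np.exp(1j * rand_phases)) ** 2
    enhancement = peak / max(rand_i.mean(), np.finfo(float).tiny)
    selective = bool(np.argmax(at_emitters) == target_index)
    return FocusRecord(
        target_index=int(target_index),
        phases=np.asarray(phases, dtype=float),
        emitter_intensity=at_emitters,
        probe_intensity=at_probes,
        snr=float(snr),
        snr_std=float(snr_std),
        enhancement=float(enhancement),
        selective=selective,
    )


def _normalized_variance(frame: np.ndarray, highpass_sigma: float | None) -> float:
    """Spatial variance of the (optionally high-passed) frame over squared mean.

    Normalizing by the squared raw mean makes the score a contrast-squared
    measure, insensitive to the extra total fluorescence a successful focus
    generates.
    """
    mean = frame.mean()
    if mean <= 0:
        raise ValueError("cannot score a zero-mean epi frame")
    work = high_pass_image(frame, highpass_sigma) if highpass_sigma else frame
    return float(work.var() / mean**2)


def epi_variance_validation(
    candidate_frames: np.ndarray,
    random_frames: np.ndarray,
    highpass_sigma: float | None = None,
    theta_focus: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Non-invasive focus verdicts from epi-detected frames.

    Parameters
    ----------
    candidate_frames : (K, rows, cols) epi frames, one per candidate conjugate
        pattern.
    random_frames : (M, rows, cols) epi frames under random illumination,
        setting the score baseline (median normalized variance).
    highpass_sigma : optional Gaussian scale for background removal before
        scoring.
    theta_focus : score threshold for the "focus" verdict.

    Returns
    -------
    scores, verdicts : normalized-variance scores (baseline-relative) and
        boolean focus verdicts per candidate.
    """
    candidate_frames = np.asarray(candidate_frames, dtype=float)
    random_frames = np.asarray(random_frames, dtype=float)
    if candidate_frames.size == 0:
        raise ValueError("empty candidate frame stack")
    if random_frames.size == 0:
        raise ValueError("empty random-illumination baseline stack")
    baseline = np.median(
        [_normalized_variance(f, highpass_sigma) for f in random_frames]
    )
    scores = np.array(
        [_normalized_variance(f, highpass_sigma) / baseline for f in candidate_frames]
    )
    return scores, scores > theta_focus
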