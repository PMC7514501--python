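"""Synthetic resting-state BOLD cohorts with planted community structure.

The generator emulates the statistical shape of a band-pass-filtered
resting-state acquisition: per subject, one latent band-limited Gaussian
signal per community (and per hidden connectivity state), mixed into every
ROI of that community together with private band-limited noise.  The planted
community partition is the ground truth against which the downstream
clustering pipeline is evaluated.

Defaults mirror a 31-subject cohort of 160 ROIs sampled every 0.475 s for
943 time points, band-limited to 0.01-0.08 Hz, with six communities of
sizes 34/21/32/33/22/18.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = ["CohortSpec", "SyntheticCohort", "generate_cohort", "write_cohort", "read_cohort"]

DEFAULT_COMMUNITY_SIZES = (34, 21, 32, 33, 22, 18)


@dataclasses.dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic multi-subject BOLD cohort.

    Attributes
    ----------
    n_subjects, n_rois, n_timepoints : int
        Cohort dimensions.
    tr : float
        Sampling interval in seconds.
    band : tuple of float
        Retained frequency band (Hz); all signals are band-limited to it.
    community_sizes : tuple of int
        Planted community sizes; must sum to ``n_rois``.
    within_strength : float
        Mixing coefficient of the shared community signal.
    noise_strength : float
        Mixing coefficient of each ROI's private noise.
    n_states : int
        Number of hidden connectivity states (1 = stationary coupling).
    state_dwell_mean : float
        Mean dwell time of the hidden-state Markov chain, in time points.
    seed : int
        RNG seed; identical spec + seed reproduces the cohort bit-exactly.
    """

    n_subjects: int = 31
    n_rois: int = 160
    n_timepoints: int = 943
    tr: float = 0.475
    band: tuple[float, float] = (0.01, 0.08)
    community_sizes: tuple[int, ...] = DEFAULT_COMMUNITY_SIZES
    within_strength: float = 0.8
    noise_strength: float = 0.4
    n_states: int = 1
    state_dwell_mean: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_rois < 1 or self.n_timepoints < 2:
            raise ValueError("cohort dimensions must be positive (n_timepoints >= 2)")
        sizes = tuple(int(s) for s in self.community_sizes)
        object.__setattr__(self, "community_sizes", sizes)
        if any(s < 1 for s in sizes):
            raise ValueError("community_sizes must be positive")
        if sum(sizes) != self.n_rois:
            raise ValueError(
                f"community_sizes sum to {sum(sizes)}, expected n_rois={self.n_rois}"
            )
        if self.within_strength < 0 or self.noise_strength < 0:
            raise ValueError("within_strength and noise_strength must be >= 0")
        lo, hi = self.band
        nyquist = 1.0 / (2.0 * self.tr)
        if not (0 <= lo < hi < nyquist):
            raise ValueError(
                f"band must satisfy 0 <= low < high < Nyquist ({nyquist:.4g} Hz), got {self.band}"
            )
        if self.n_states < 1:
            raise ValueError("n_states must be >= 1")
        if self.n_states > 1 and self.state_dwell_mean <= 1:
            raise ValueError("state_dwell_mean must exceed 1 time point when n_states > 1")

    @property
    def true_labels(self) -> np.ndarray:
        """Community index (0-based) per ROI, in block order."""
        return np.repeat(np.arange(len(self.community_sizes)), self.community_sizes)


@dataclasses.dataclass(frozen=True)
class SyntheticCohort:
    """Generated cohort: per-subject BOLD matrices plus ground truth."""

    bold: tuple[np.ndarray, ...]  # each n_timepoints x n_rois
    true_labels: np.ndarray  # community index per ROI
    state_sequence: tuple[np.ndarray, ...]  # hidden-state index per time point
    spec: CohortSpec

    @property
    def n_subjects(self) -> int:
        return len(self.bold)


def _band_limit(white: np.ndarray, tr: float, band: tuple[float, float]) -> np.ndarray:
    """Restrict columns of ``white`` (time x series) to ``band`` by FFT masking.

    Bins strictly outside the band (and the DC bin) are zeroed; the result is
    standardized column-wise to zero mean and unit population SD.
    """
    n = white.shape[0]
    freqs = np.fft.rfftfreq(n, d=tr)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    spectrum = np.fft.rfft(white, axis=0)
    spectrum[~mask] = 0.0
    out = np.fft.irfft(spectrum, n=n, axis=0)
    out -= out.mean(axis=0)
    sd = out.std(axis=0)
    if np.any(sd == 0):
        raise RuntimeError("band-limiting produced a constant series; widen the band")
    return out / sd


def _markov_states(rng: np.random.Generator, n_timepoints: int, n_states: int,
                   dwell_mean: float) -> np.ndarray:
    """Hidden-state chain with uniform off-diagonal transitions.

    The self-transition probability is 1 - 1/dwell_mean, giving a geometric
    dwell-time distribution with the requested mean.
    """
    if n_states == 1:
        return np.zeros(n_timepoints, dtype=np.int64)
    p_leave = 1.0 / dwell_mean
    states = np.empty(n_timepoints, dtype=np.int64)
    states[0] = rng.integers(n_states)
    for t in range(1, n_timepoints):
        if rng.random() < p_leave:
            others = [s for s in range(n_states) if s != states[t - 1]]
            states[t] = others[rng.integers(n_states - 1)]
        else:
            states[t] = states[t - 1]
    return states


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate a cohort of band-limited BOLD matrices with planted communities.

    For each subject, one latent signal is drawn per (community, hidden state)
    pair; ROI *i* in community *c* at time *t* is
    ``within_strength * latent[c, state(t), t] + noise_strength * private[i, t]``,
    with latents and private noise both band-limited white Gaussian noise.
    """
    rng = np.random.default_rng(spec.seed)
    n_comm = len(spec.community_sizes)
    labels = spec.true_labels
    bold: list[np.ndarray] = []
    state_seqs: list[np.ndarray] = []
    for _ in range(spec.n_subjects):
        states = _markov_states(rng, spec.n_timepoints, spec.n_states, spec.state_dwell_mean)
        # latents: time x (community, state)
        latents = _band_limit(
            rng.standard_normal((spec.n_timepoints, n_comm * spec.n_states)),
            spec.tr, spec.band,
        ).reshape(spec.n_timepoints, n_comm, spec.n_states)
        private = _band_limit(
            rng.standard_normal((spec.n_timepoints, spec.n_rois)), spec.tr, spec.band
        )
        t_idx = np.arange(spec.n_timepoints)
        active = latents[t_idx, :, states]  # time x community
        subject = (spec.within_strength * active[:, labels]
                   + spec.noise_strength * private)
        bold.append(subject)
        state_seqs.append(states)
    cohort = SyntheticCohort(tuple(bold), labels, tuple(state_seqs), spec)
    for b in cohort.bold:
        if not np.all(np.isfinite(b)):
            raise RuntimeError("generated BOLD contains non-finite values")
    return cohort


def write_cohort(cohort: SyntheticCohort, directory: str | Path) -> Path:
    """Write a cohort as per-subject TSVs, a template TSV and a JSON manifest.

    Returns the manifest path.  Matrices are written at full double precision
    so that re-reading reproduces them bit-exactly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    roi_ids = [f"roi_{i + 1:03d}" for i in range(cohort.spec.n_rois)]
    files = []
    for s, mat in enumerate(cohort.bold):
        path = directory / f"subject_{s + 1:02d}.tsv"
        with path.open("w") as fh:
            fh.write("\t".join(roi_ids) + "\n")
            for row in mat:
                fh.write("\t".join(format(v, ".17g") for v in row) + "\n")
        files.append(path.name)
    template_path = directory / "template.tsv"
    with template_path.open("w") as fh:
        fh.write("roi_index\troi_name\tnetwork_label\n")
        for i, lab in enumerate(cohort.true_labels):
            fh.write(f"{i + 1}\t{roi_ids[i]}\tcommunity_{int(lab) + 1}\n")
    manifest = {
        "spec": dataclasses.asdict(cohort.spec),
        "seed": cohort.spec.seed,
        "subject_files": files,
        "template": template_path.name,
    }
    manifest_path = directory / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path


def read_cohort(directory: str | Path) -> SyntheticCohort:
    """Re-read a cohort written by :func:`write_cohort`."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    spec_dict = dict(manifest["spec"])
    spec_dict["band"] = tuple(spec_dict["band"])
    spec_dict["community_sizes"] = tuple(spec_dict["community_sizes"])
    spec = CohortSpec(**spec_dict)
    bold = []
    for name in manifest["subject_files"]:
        bold.append(np.loadtxt(directory / name, delimiter="\t", skiprows=1))
    labels = []
    with (directory / manifest["template"]).open() as fh:
        next(fh)
        for line in fh:
            labels.append(int(line.rstrip("\n").split("\t")[2].rsplit("_", 1)[1]) - 1)
    return SyntheticCohort(tuple(bold), np.asarray(labels), tuple(), spec)
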