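"""Electron energy spectra: loading, sampling and LINAC-like synthesis.

The irradiation source is a binned electron energy distribution, such as
one extracted from a phase space behind a 6 MV photon beam.  Spectra are
plain two-column text (bin upper edge in MeV, weight); the synthesizer
produces a download-free stand-in for a measured LINAC spectrum pinned to
a stated fraction of electrons below 1 MeV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SpectrumHistogram",
    "load_spectrum",
    "save_spectrum",
    "sample_energies",
    "synth_linac_spectrum",
    "truncate_spectrum",
]

_NORMALIZATION_TOL = 1e-12


@dataclass(frozen=True)
class SpectrumHistogram:
    """Binned electron energy distribution.

    ``bin_edges`` are ascending energies in MeV (length K+1, first edge is
    the spectrum floor, usually 0); ``probabilities`` (length K) sum to 1.
    """

    bin_edges: np.ndarray
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        probs = np.asarray(self.probabilities, dtype=float)
        if edges.ndim != 1 or edges.size < 2:
            raise ValueError("need at least one bin (two edges)")
        if probs.shape != (edges.size - 1,):
            raise ValueError("probabilities must have one entry per bin")
        if not np.all(np.diff(edges) > 0):
            raise ValueError("bin edges must be strictly increasing")
        if np.any(probs < 0):
            raise ValueError("probabilities must be non-negative")
        total = probs.sum()
        if total <= 0:
            raise ValueError("spectrum has zero total weight")
        if abs(total - 1.0) > _NORMALIZATION_TOL:
            probs = probs / total
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "probabilities", probs)

    @property
    def n_bins(self) -> int:
        return self.probabilities.size

    def cdf(self, energy_mev: float) -> float:
        """Cumulative probability below ``energy_mev`` (uniform within bins)."""
        edges, probs = self.bin_edges, self.probabilities
        if energy_mev <= edges[0]:
            return 0.0
        if energy_mev >= edges[-1]:
            return 1.0
        k = int(np.searchsorted(edges, energy_mev, side="right")) - 1
        frac = (energy_mev - edges[k]) / (edges[k + 1] - edges[k])
        return float(probs[:k].sum() + probs[k] * frac)

    def mean_energy(self) -> float:
        """Mean energy in MeV under the uniform-within-bin density."""
        mids = 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])
        return float(np.dot(mids, self.probabilities))


def load_spectrum(path) -> SpectrumHistogram:
    """Read a two-column text spectrum: bin upper edge (MeV), weight.

    Lines starting with ``#`` are comments; fields may be separated by
    whitespace or commas.  The first bin's lower edge is implicitly 0.
    Weights are renormalized to probabilities.
    """
    uppers: list[float] = []
    weights: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.replace(",", " ").split()
            if len(fields) < 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 'edge weight', got {raw!r}"
                )
            try:
                edge, weight = float(fields[0]), float(fields[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric field") from exc
            if weight < 0:
                raise ValueError(f"{path}:{lineno}: negative weight {weight}")
            if uppers and edge <= uppers[-1]:
                raise ValueError(
                    f"{path}:{lineno}: bin edges must ascend "
                    f"({edge} after {uppers[-1]})"
                )
            uppers.append(edge)
            weights.append(weight)
    if not uppers:
        raise ValueError(f"{path}: no spectrum bins found")
    edges = np.concatenate([[0.0], uppers])
    return SpectrumHistogram(bin_edges=edges, probabilities=np.array(weights))


def save_spectrum(spec: SpectrumHistogram, path) -> None:
    """Write a spectrum in the two-column text format read by load_spectrum."""
    with open(path, "w") as fh:
        fh.write("# bin_upper_edge_MeV probability\n")
        for edge, p in zip(spec.bin_edges[1:], spec.probabilities):
            fh.write(f"{float(edge)!r} {float(p)!r}\n")


def sample_energies(
    spec: SpectrumHistogram, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` electron energies (MeV): multinomial over bins, uniform
    within the selected bin on (lower, upper]."""
    if n < 1:
        raise ValueError("n must be >= 1")
    k = rng.choice(spec.n_bins, size=n, p=spec.probabilities)
    lo = spec.bin_edges[k]
    hi = spec.bin_edges[k + 1]
    # upper-edge anchored so energies stay strictly above the spectrum floor
    return hi - rng.random(n) * (hi - lo)


def synth_linac_spectrum(
    frac_below_1mev: float = 0.52,
    e_max: float = 6.0,
    n_bins: int = 60,
    shape_scale_mev: float = 0.5,
    frac_is_energy_weighted: bool = False,
) -> SpectrumHistogram:
    """Synthesize a 6-MV-LINAC-like electron spectrum.

    The density decreases with energy (exponential shape with scale
    ``shape_scale_mev``) over (0, e_max] and is piecewise rescaled so the
    cumulative probability at exactly 1 MeV equals ``frac_below_1mev``.
    With ``frac_is_energy_weighted`` the pin applies to the fraction of
    total *energy* carried by sub-MeV electrons instead of the fraction of
    electrons.  Deterministic given its parameters.
    """
    if not 0.0 < frac_below_1mev < 1.0:
        raise ValueError("frac_below_1mev must be in (0, 1)")
    if e_max <= 1.0:
        raise ValueError("e_max must exceed 1 MeV")
    if n_bins < 2:
        raise ValueError("need at least 2 bins")

    edges = np.unique(np.concatenate([np.linspace(0.0, e_max, n_bins + 1), [1.0]]))
    lo, hi = edges[:-1], edges[1:]
    # bin mass of the exponential density, before pinning
    w = np.exp(-lo / shape_scale_mev) - np.exp(-hi / shape_scale_mev)
    below = hi <= 1.0

    if frac_is_energy_weighted:
        mids = 0.5 * (lo + hi)
        e_below = float(np.dot(w[below], mids[below]))
        e_above = float(np.dot(w[~below], mids[~below]))
        # scale the two groups so sub-MeV electrons carry frac of the energy
        alpha = frac_below_1mev / e_below
        beta = (1.0 - frac_below_1mev) / e_above
    else:
        alpha = frac_below_1mev / float(w[below].sum())
        beta = (1.0 - frac_below_1mev) / float(w[~below].sum())
    w = np.where(below, w * alpha, w * beta)
    return SpectrumHistogram(bin_edges=edges, probabilities=w / w.sum())


def truncate_spectrum(spec: SpectrumHistogram, e_cut: float) -> SpectrumHistogram:
    """Drop all bins above ``e_cut`` MeV and renormalize.

    Mirrors the argument that electrons above ~1 MeV have ranges far
    exceeding the molecule and contribute negligibly to local deposition.
    """
    keep = spec.bin_edges[1:] <= e_cut + 1e-15
    if not np.any(keep):
        raise ValueError(f"e_cut={e_cut} MeV removes every bin")
    k = int(np.sum(keep))
    return SpectrumHistogram(
        bin_edges=spec.bin_edges[: k + 1],
        probabilities=spec.probabilities[:k],
    )
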