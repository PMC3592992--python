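"""Sample allele frequency spectra.

A spectrum is a probability vector over sample allele counts: classes
``0..n`` for a derived (unfolded) spectrum of a pool of ``n`` chromosomes, or
``0..n//2`` for a folded (minor-allele) spectrum.  Class 0 holds the
monomorphic-ancestral mass, so spectra here always integrate the density of
segregating sites as well as their frequency pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Spectrum",
    "fold_spectrum",
    "unfold_spectrum",
    "read_spectrum_file",
    "write_spectrum_file",
]

_SUM_TOL = 1e-6


@dataclass(frozen=True)
class Spectrum:
    """A probability vector over sample allele-count classes.

    Parameters
    ----------
    probs : array-like
        Non-negative class probabilities, length ``n + 1`` (unfolded) or
        ``n // 2 + 1`` (folded).  Renormalized exactly on construction; the
        input must already sum to 1 within 1e-6.
    n : int
        Haploid pool size (number of pooled chromosomes).
    folded : bool
        Whether classes index minor-allele counts rather than derived counts.
    """

    probs: np.ndarray
    n: int
    folded: bool = False

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        expected = self.n // 2 + 1 if self.folded else self.n + 1
        if probs.ndim != 1 or probs.size != expected:
            raise ValueError(
                f"spectrum for n={self.n} ({'folded' if self.folded else 'unfolded'}) "
                f"needs {expected} classes, got {probs.size}"
            )
        if np.any(probs < 0):
            raise ValueError("spectrum entries must be non-negative")
        total = probs.sum()
        if not np.isfinite(total) or abs(total - 1.0) > _SUM_TOL:
            raise ValueError(f"spectrum must sum to 1 (got {total!r})")
        object.__setattr__(self, "probs", probs / total)

    @property
    def n_classes(self) -> int:
        return self.probs.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Spectrum):
            return NotImplemented
        return (
            self.n == other.n
            and self.folded == other.folded
            and np.array_equal(self.probs, other.probs)
        )


def fold_spectrum(spec: Spectrum) -> Spectrum:
    """Collapse a derived spectrum onto minor-allele classes.

    Class ``m`` receives ``p[m] + p[n-m]`` (just ``p[m]`` when ``m == n - m``).
    """
    if spec.folded:
        return spec
    n = spec.n
    k = n // 2
    out = np.zeros(k + 1)
    for m in range(k + 1):
        if m != n - m:
            out[m] = spec.probs[m] + spec.probs[n - m]
        else:
            out[m] = spec.probs[m]
    return Spectrum(out, n, folded=True)


def unfold_spectrum(spec: Spectrum) -> Spectrum:
    """Lift a folded spectrum to derived classes by symmetric mass splitting.

    Each minor-class mass is split equally between counts ``m`` and ``n - m``.
    This is the maximum-entropy inverse of :func:`fold_spectrum` and is used
    when a derived spectrum is required (e.g. the sweep transform) but only a
    folded one was estimated.
    """
    if not spec.folded:
        return spec
    n = spec.n
    out = np.zeros(n + 1)
    for m in range(spec.n_classes):
        if m != n - m:
            out[m] = spec.probs[m] / 2.0
            out[n - m] = spec.probs[m] / 2.0
        else:
            out[m] = spec.probs[m]
    return Spectrum(out, n, folded=False)


def read_spectrum_file(path, n: int | None = None, folded: bool | None = None) -> Spectrum:
    """Read a whitespace-separated spectrum file.

    Lines starting with ``#`` are comments; a header written by
    :func:`write_spectrum_file` records ``n`` and foldedness and is honored
    when present.  Explicit ``n``/``folded`` arguments override the header.
    Values must be non-negative and sum to 1 within 1e-6 (then renormalized).
    """
    values: list[float] = []
    header_n = None
    header_folded = None
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                for tok in line[1:].split():
                    if tok.startswith("n="):
                        header_n = int(tok[2:])
                    elif tok == "folded":
                        header_folded = True
                    elif tok == "unfolded":
                        header_folded = False
                continue
            for tok in line.split():
                try:
                    values.append(float(tok))
                except ValueError as exc:
                    raise ValueError(f"{path}: non-numeric spectrum entry {tok!r}") from exc
    if not values:
        raise ValueError(f"{path}: empty spectrum file")
    arr = np.asarray(values)
    if np.any(arr < 0):
        raise ValueError(f"{path}: negative spectrum entry")
    if abs(arr.sum() - 1.0) > _SUM_TOL:
        raise ValueError(f"{path}: spectrum sums to {arr.sum()!r}, expected 1 +/- {_SUM_TOL}")
    if folded is None:
        folded = header_folded if header_folded is not None else False
    if n is None:
        n = header_n if header_n is not None else (
            # without any metadata, infer n from the class count
            (arr.size - 1) if not folded else 2 * (arr.size - 1)
        )
    return Spectrum(arr, n=n, folded=folded)


def write_spectrum_file(spec: Spectrum, path, extra_header: str | None = None) -> None:
    """Write one line of full-precision probabilities plus a ``#`` header."""
    with open(path, "w") as fh:
        if extra_header:
            fh.write(f"# {extra_header}\n")
        fh.write(f"# n={spec.n} {'folded' if spec.folded else 'unfolded'}\n")
        fh.write(" ".join(repr(float(p)) for p in spec.probs) + "\n")
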