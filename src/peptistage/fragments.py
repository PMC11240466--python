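"""Fragment-ion arithmetic for peptide identification from tandem MS.

Collision-induced dissociation of a protonated peptide cleaves the backbone
amide bonds, producing an N-terminal b-ion series and a C-terminal y-ion
series.  Matching the predicted monoisotopic b/y ladders of a candidate
sequence against an observed (composite) MS2 spectrum is the standard way to
confirm a peptide assignment when database search is ambiguous.

All masses are monoisotopic and singly protonated:

    b_k = sum(residue masses 1..k) + m_H
    y_k = sum(residue masses n-k+1..n) + m_H2O + m_H

where ``m_H`` is the mass of a hydrogen atom (not the bare proton); with the
hydrogen-atom constant the ladders agree with standard fragment-ion
calculators to better than 1e-4 Da.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Peptide",
    "IonSeries",
    "CompositeSpectrum",
    "FragmentMatch",
    "ion_series",
    "sum_spectra",
    "match_fragments",
    "isoelectric_point",
    "RESIDUE_MASS",
    "M_H",
    "M_H2O",
]

# Standard monoisotopic residue (amino-acid minus water) masses in Da,
# IUPAC/Unimod values to 7 decimals.
RESIDUE_MASS: dict[str, float] = {
    "G": 57.0214637,
    "A": 71.0371138,
    "S": 87.0320284,
    "P": 97.0527639,
    "V": 99.0684139,
    "T": 101.0476785,
    "C": 103.0091845,
    "L": 113.0840640,
    "I": 113.0840640,
    "N": 114.0429275,
    "D": 115.0269430,
    "Q": 128.0585775,
    "K": 128.0949630,
    "E": 129.0425931,
    "M": 131.0404846,
    "H": 137.0589119,
    "F": 147.0684139,
    "R": 156.1011110,
    "Y": 163.0633285,
    "W": 186.0793130,
}

M_H = 1.0078250319  # hydrogen atom, Da
M_H2O = 18.0105646863  # water, Da

# EMBOSS pKa values; used for the informational isoelectric point only.
PKA_SETS: dict[str, dict[str, float]] = {
    "emboss": {
        "n_term": 8.6,
        "c_term": 3.6,
        "C": 8.5,
        "D": 3.9,
        "E": 4.1,
        "H": 6.5,
        "K": 10.8,
        "R": 12.5,
        "Y": 10.1,
    },
}
_ACIDIC = {"C", "D", "E", "Y"}
_BASIC = {"H", "K", "R"}


@dataclass(frozen=True)
class Peptide:
    """A peptide over the 20 standard one-letter amino-acid codes."""

    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("peptide sequence is empty")
        for i, aa in enumerate(self.sequence):
            if aa not in RESIDUE_MASS:
                raise ValueError(
                    f"unknown residue {aa!r} at position {i + 1} in {self.sequence!r}"
                )

    @property
    def n(self) -> int:
        return len(self.sequence)

    @property
    def monoisotopic_mass(self) -> float:
        """Neutral monoisotopic mass of the peptide."""
        return sum(RESIDUE_MASS[aa] for aa in self.sequence) + M_H2O


@dataclass(frozen=True)
class IonSeries:
    """Singly protonated monoisotopic b and y ladders, b_1..b_n / y_1..y_n."""

    peptide: Peptide
    b: tuple[float, ...]
    y: tuple[float, ...]

    def as_rows(self) -> list[dict]:
        """Rows in the layout of a fragment-ion calculator table:
        one row per residue with b_k (N-terminal index k) and y_{n-k+1}."""
        n = self.peptide.n
        return [
            {
                "seq": self.peptide.sequence[k - 1],
                "b_index": k,
                "b": self.b[k - 1],
                "y": self.y[n - k],
                "y_index": n - k + 1,
            }
            for k in range(1, n + 1)
        ]


def ion_series(peptide: Peptide | str) -> IonSeries:
    """Compute the singly protonated monoisotopic b/y ion ladders.

    Parameters
    ----------
    peptide
        A :class:`Peptide` or a plain sequence string.

    Returns
    -------
    IonSeries
        ``b[k-1]`` is b_k, ``y[k-1]`` is y_k.  By construction
        ``b_n + m_H2O == y_n`` (both equal MH+ of the intact peptide) and
        ``b_k + y_{n-k} == y_n + m_H`` for every internal cleavage site.
    """
    if isinstance(peptide, str):
        peptide = Peptide(peptide)
    masses = [RESIDUE_MASS[aa] for aa in peptide.sequence]
    b = tuple(np.cumsum(masses) + M_H)
    y = tuple(np.cumsum(masses[::-1]) + M_H2O + M_H)
    return IonSeries(peptide=peptide, b=b, y=y)


@dataclass
class CompositeSpectrum:
    """A binned sum of one or more MS2 peak lists.

    Summing spectra acquired at several collision energies (and gases)
    increases fragment coverage: ions produced efficiently at only one
    energy still appear in the composite.
    """

    bin_width: float
    bins: dict[int, float] = field(default_factory=dict)  # bin index -> intensity
    n_spectra: int = 0

    @property
    def total_intensity(self) -> float:
        return float(sum(self.bins.values()))

    def peaks(self) -> np.ndarray:
        """(mz, intensity) array, mz at bin centers, sorted by mz."""
        idx = np.array(sorted(self.bins), dtype=float)
        mz = (idx + 0.5) * self.bin_width
        inten = np.array([self.bins[int(i)] for i in idx])
        return np.column_stack([mz, inten])


def sum_spectra(spectra: list[np.ndarray], bin_width: float = 0.01) -> CompositeSpectrum:
    """Sum MS2 peak lists into a composite spectrum on a fixed m/z grid.

    Each spectrum is an (n, 2) array of (mz, intensity).  Peaks fall into
    half-open bins ``[i*bin_width, (i+1)*bin_width)``; intensities are summed,
    so total intensity is conserved exactly.
    """
    if not spectra:
        raise ValueError("need at least one spectrum")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    comp = CompositeSpectrum(bin_width=bin_width)
    for spec in spectra:
        arr = np.asarray(spec, dtype=float)
        if arr.size == 0:
            comp.n_spectra += 1
            continue
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("spectrum must be an (n, 2) array of (mz, intensity)")
        idx = np.floor(arr[:, 0] / bin_width).astype(int)
        for i, inten in zip(idx, arr[:, 1]):
            comp.bins[int(i)] = comp.bins.get(int(i), 0.0) + float(inten)
        comp.n_spectra += 1
    return comp


@dataclass(frozen=True)
class FragmentMatch:
    ion: str  # "b3" / "y5"
    predicted_mz: float
    observed_mz: float
    error_da: float
    error_ppm: float


def match_fragments(
    series: IonSeries, spectrum: CompositeSpectrum, tol: float = 0.01
) -> tuple[list[FragmentMatch], float]:
    """Match predicted b/y ions to the nearest observed composite bin.

    One observed bin may account for several predicted ions (b/y ladders of
    short peptides can collide in m/z).  Coverage is the matched fraction of
    the 2n predicted ions.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    observed = spectrum.peaks()
    matches: list[FragmentMatch] = []
    predicted = [(f"b{k + 1}", m) for k, m in enumerate(series.b)]
    predicted += [(f"y{k + 1}", m) for k, m in enumerate(series.y)]
    for label, pred in predicted:
        if observed.size == 0:
            continue
        j = int(np.argmin(np.abs(observed[:, 0] - pred)))
        obs = float(observed[j, 0])
        err = obs - pred
        if abs(err) <= tol:
            matches.append(
                FragmentMatch(
                    ion=label,
                    predicted_mz=float(pred),
                    observed_mz=obs,
                    error_da=float(err),
                    error_ppm=float(err / pred * 1e6),
                )
            )
    coverage = len(matches) / (2 * series.peptide.n)
    return matches, coverage


def _net_charge(sequence: str, ph: float, pka: dict[str, float]) -> float:
    charge = 1.0 / (1.0 + 10 ** (ph - pka["n_term"]))
    charge -= 1.0 / (1.0 + 10 ** (pka["c_term"] - ph))
    for aa in sequence:
        if aa in _BASIC and aa in pka:
            charge += 1.0 / (1.0 + 10 ** (ph - pka[aa]))
        elif aa in _ACIDIC and aa in pka:
            charge -= 1.0 / (1.0 + 10 ** (pka[aa] - ph))
    return charge


def isoelectric_point(
    peptide: Peptide | str, pka_set: str | dict[str, float] = "emboss"
) -> float:
    """Isoelectric point by bisection on the Henderson-Hasselbalch net charge.

    The result depends on the pKa table; it is informational output, not an
    identification criterion.
    """
    if isinstance(peptide, str):
        peptide = Peptide(peptide)
    pka = PKA_SETS[pka_set] if isinstance(pka_set, str) else pka_set
    lo, hi = 0.0, 14.0
    # net charge is strictly decreasing in pH
    while hi - lo > 1e-9:
        mid = (lo + hi) / 2
        if _net_charge(peptide.sequence, mid, pka) > 0:
            lo = mid
        else:
            hi = mid
    pi = (lo + hi) / 2
    assert abs(_net_charge(peptide.sequence, pi, pka)) < 1e-6
    return pi
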