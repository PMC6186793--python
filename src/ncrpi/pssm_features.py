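"""Pseudo-Zernike moment descriptors of position-specific scoring matrices.

A PSSM is the r x 20 log-odds profile PSI-BLAST produces for a protein of
length r: entry ``p[i, j]`` scores amino acid ``j`` (PSI-BLAST column order)
at sequence position ``i`` and encodes per-position evolutionary
conservation. To turn a variable-size profile into a fixed-length
descriptor, the profile is treated as a grey-level image: log-odds are
squashed into (0, 1) with a logistic transform, the r x 20 grid is mapped
into the closed unit disk, and the magnitudes ``|M_ab|`` of its
pseudo-Zernike moments are collected. Moment magnitudes are invariant under
rotation of the image about the disk centre and form a compact, ordered
family of shape descriptors widely used in image analysis.

The pseudo-Zernike basis of order ``a`` and repetition ``b`` (|b| <= a) is

    V_ab(x, y) = R_ab(rho) * exp(j*b*theta),    rho^2 = x^2 + y^2 <= 1,

with real radial polynomials

    R_ab(rho) = sum_{t=0}^{a-|b|} Z(a, |b|, t) * rho^(a-t),
    Z(a, |b|, t) = (-1)^t (2a+1-t)! / [ t! (a-|b|-t)! (a+|b|+1-t)! ].

The basis is orthogonal over the unit disk with normalization
``pi / (a + 1)``, and the moment of an image f is

    M_ab = (a+1)/pi * integral of f(x, y) * conj(V_ab) over the disk,

discretized here as a midpoint quadrature over grid cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

#: PSI-BLAST ASCII PSSM column order of the 20 canonical amino acids.
AA_ORDER = "ARNDCQEGHILKMFPSTWYV"

N_AMINO_ACIDS = 20


@dataclass(frozen=True)
class Pssm:
    """Position-specific scoring matrix: r rows (positions) x 20 columns.

    Columns follow :data:`AA_ORDER`. Entries are real scores (raw PSI-BLAST
    log-odds, or values in (0,1) after :func:`normalize_pssm`).
    """

    scores: np.ndarray
    protein_id: str | None = None

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        if scores.ndim != 2 or scores.shape[1] != N_AMINO_ACIDS:
            raise ValueError(
                f"PSSM must be 2-D with {N_AMINO_ACIDS} columns, got shape "
                f"{scores.shape}"
            )
        if scores.shape[0] < 1:
            raise ValueError("PSSM must have at least one row")
        if not np.all(np.isfinite(scores)):
            raise ValueError("PSSM entries must be finite")
        object.__setattr__(self, "scores", scores)

    @property
    def length(self) -> int:
        return self.scores.shape[0]


@dataclass(frozen=True)
class UnitDiskImage:
    """Flattened image sampled at cell centres inside the closed unit disk.

    ``values[c]`` is the image value at centre ``(x[c], y[c])``;
    ``pixel_area`` is the midpoint-quadrature weight dx*dy shared by all
    cells.
    """

    values: np.ndarray
    x: np.ndarray
    y: np.ndarray
    pixel_area: float

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float).ravel()
        x = np.asarray(self.x, dtype=float).ravel()
        y = np.asarray(self.y, dtype=float).ravel()
        if not (values.shape == x.shape == y.shape):
            raise ValueError("values, x and y must have equal lengths")
        if values.size == 0:
            raise ValueError("image has no cells inside the unit disk")
        if np.any(x * x + y * y > 1.0 + 1e-12):
            raise ValueError("all cells must satisfy x^2 + y^2 <= 1")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)


@dataclass(frozen=True)
class PzmFeatureVector:
    """Moment magnitudes |M_ab| for a = 1..alpha_max, b = 0..a (lexicographic)."""

    magnitudes: np.ndarray
    alpha_max: int

    def __post_init__(self) -> None:
        mags = np.asarray(self.magnitudes, dtype=float).ravel()
        expected = feature_length(self.alpha_max)
        if mags.size != expected:
            raise ValueError(
                f"expected {expected} magnitudes for alpha_max={self.alpha_max}, "
                f"got {mags.size}"
            )
        if np.any(mags < 0) or not np.all(np.isfinite(mags)):
            raise ValueError("magnitudes must be finite and nonnegative")
        object.__setattr__(self, "magnitudes", mags)


@dataclass
class PzmBasisCache:
    """Memoizes radial coefficient vectors keyed by (alpha, |beta|).

    Cached vectors are computed by exactly the same code path as uncached
    ones, so cached and fresh results agree bitwise.
    """

    _radial: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)

    def radial_coefficients(self, alpha: int, beta_abs: int) -> np.ndarray:
        key = (alpha, beta_abs)
        if key not in self._radial:
            coeffs = np.array(
                [radial_coefficient(alpha, beta_abs, t)
                 for t in range(alpha - beta_abs + 1)]
            )
            coeffs.setflags(write=False)
            self._radial[key] = coeffs
        return self._radial[key]


def feature_length(alpha_max: int) -> int:
    """Number of (a, b) pairs with 1 <= a <= alpha_max, 0 <= b <= a."""
    if alpha_max < 1:
        raise ValueError("alpha_max must be >= 1")
    return sum(a + 1 for a in range(1, alpha_max + 1))


def moment_pairs(alpha_max: int) -> list[tuple[int, int]]:
    """Lexicographic (a, b) index pairs backing :class:`PzmFeatureVector`."""
    if alpha_max < 1:
        raise ValueError("alpha_max must be >= 1")
    return [(a, b) for a in range(1, alpha_max + 1) for b in range(a + 1)]


def read_psiblast_pssm(path) -> Pssm:
    """Parse the ASCII PSSM that ``psiblast -out_ascii_pssm`` writes.

    Only the r x 20 log-odds block is read; the weighted-percentage block
    and the footer statistics are ignored. Columns are reordered to
    :data:`AA_ORDER` using the file's own header, so non-standard column
    orders are tolerated.
    """
    with open(path) as handle:
        lines = handle.read().splitlines()

    header_cols: list[str] | None = None
    header_idx = None
    for i, line in enumerate(lines):
        tokens = line.split()
        if len(tokens) >= N_AMINO_ACIDS and all(
            t in AA_ORDER and len(t) == 1 for t in tokens[:N_AMINO_ACIDS]
        ):
            header_cols = tokens[:N_AMINO_ACIDS]
            header_idx = i
            break
    if header_cols is None or sorted(header_cols) != sorted(AA_ORDER):
        raise ValueError(f"{path}: no PSI-BLAST PSSM column header found")

    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[header_idx + 1:], start=header_idx + 2):
        tokens = line.split()
        if not tokens:
            break
        if not tokens[0].lstrip("-").isdigit():
            break
        fields = tokens[2:]
        # full PSI-BLAST rows carry 20 log-odds + 20 percentages + 2 stats
        if len(fields) >= 2 * N_AMINO_ACIDS:
            fields = fields[:N_AMINO_ACIDS]
        elif len(fields) != N_AMINO_ACIDS:
            raise ValueError(
                f"{path}: line {lineno}: expected {N_AMINO_ACIDS} score fields, "
                f"got {len(fields)}"
            )
        try:
            rows.append([float(f) for f in fields])
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: non-numeric score") from exc
    if not rows:
        raise ValueError(f"{path}: PSSM contains no residue rows")

    scores = np.array(rows, dtype=float)
    order = [header_cols.index(aa) for aa in AA_ORDER]
    return Pssm(scores[:, order])


def normalize_pssm(pssm: Pssm) -> Pssm:
    """Squash raw log-odds into (0, 1) entrywise with the logistic function."""
    return Pssm(expit(pssm.scores), protein_id=pssm.protein_id)


def to_unit_disk(pssm: Pssm) -> UnitDiskImage:
    """Map the r x 20 grid into the unit disk via its half-diagonal.

    Cell (i, j) goes to ``x = (2j - (C-1))/D``, ``y = (2i - (r-1))/D`` with
    C = 20 and ``D = sqrt((r-1)^2 + (C-1)^2)``, so the grid's bounding box
    is inscribed in the disk (corner cells land exactly on rho = 1) and no
    cell is discarded.
    """
    return image_from_grid(pssm.scores)


def image_from_grid(values: np.ndarray) -> UnitDiskImage:
    """Inscribe an arbitrary 2-D grid in the unit disk (half-diagonal mapping).

    Shared by :func:`to_unit_disk` and the square test images used for
    rotation-invariance checks; for a square grid the mapped coordinate set
    is itself invariant under 90-degree rotations.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.size == 0:
        raise ValueError("grid must be a nonempty 2-D array")
    r, c = values.shape
    d = math.hypot(r - 1, c - 1)
    if d == 0.0:  # 1x1 grid: single cell at the origin
        d = 1.0
    x = (2.0 * np.arange(c) - (c - 1)) / d
    y = (2.0 * np.arange(r) - (r - 1)) / d
    xx, yy = np.meshgrid(x, y)
    return UnitDiskImage(values.ravel(), xx.ravel(), yy.ravel(), (2.0 / d) ** 2)


def disk_grid(n: int, fill: float = 1.0) -> UnitDiskImage:
    """An n x n midpoint grid over [-1,1]^2 restricted to the unit disk.

    Covers the whole disk (unlike the inscribed mapping) and is the grid on
    which discrete basis orthogonality is checked.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    coords = (2.0 * np.arange(n) + 1.0 - n) / n
    xx, yy = np.meshgrid(coords, coords)
    mask = xx * xx + yy * yy <= 1.0
    values = np.full(int(mask.sum()), float(fill))
    return UnitDiskImage(values, xx[mask], yy[mask], (2.0 / n) ** 2)


def radial_coefficient(alpha: int, beta_abs: int, t: int) -> float:
    """Pseudo-Zernike radial coefficient Z(alpha, |beta|, t).

    ``(-1)^t (2a+1-t)! / [t! (a-|b|-t)! (a+|b|+1-t)!]`` evaluated in
    log-factorial space so orders well beyond 30 stay finite.
    """
    if alpha < 0 or not (0 <= beta_abs <= alpha) or not (0 <= t <= alpha - beta_abs):
        raise ValueError(
            f"invalid radial index (alpha={alpha}, |beta|={beta_abs}, t={t})"
        )
    log_num = math.lgamma(2 * alpha + 2 - t)
    log_den = (
        math.lgamma(t + 1)
        + math.lgamma(alpha - beta_abs - t + 1)
        + math.lgamma(alpha + beta_abs + 2 - t)
    )
    return (-1.0) ** t * math.exp(log_num - log_den)


def radial_polynomial(alpha: int, beta_abs: int, rho, cache: PzmBasisCache | None = None):
    """R_ab(rho) = sum_t Z(a,|b|,t) rho^(a-t); R_{a,-b} = R_{a,b} by definition.

    ``rho`` may be a scalar or array with entries in [0, 1].
    """
    rho = np.asarray(rho, dtype=float)
    if np.any(rho < 0) or np.any(rho > 1.0 + 1e-12):
        raise ValueError("rho must lie in [0, 1]")
    coeffs = (cache or PzmBasisCache()).radial_coefficients(alpha, beta_abs)
    result = np.zeros_like(rho)
    for t, z in enumerate(coeffs):
        result = result + z * rho ** (alpha - t)
    return result if result.ndim else float(result)


def pzm_basis(alpha: int, beta: int, x, y, cache: PzmBasisCache | None = None):
    """Basis value V_ab(x, y) = R_a|b|(rho) exp(j*b*theta) inside the disk."""
    if abs(beta) > alpha:
        raise ValueError(f"|beta| must be <= alpha, got ({alpha}, {beta})")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(x * x + y * y > 1.0 + 1e-12):
        raise ValueError("point outside the unit disk")
    rho = np.hypot(x, y)
    theta = np.arctan2(y, x)
    value = radial_polynomial(alpha, abs(beta), rho, cache) * np.exp(1j * beta * theta)
    return value if value.ndim else complex(value)


def pseudo_zernike_moment(
    image: UnitDiskImage, alpha: int, beta: int, cache: PzmBasisCache | None = None
) -> complex:
    """Discrete moment M_ab = (a+1)/pi * sum_c f_c conj(V_ab(x_c, y_c)) dA."""
    if abs(beta) > alpha:
        raise ValueError(f"|beta| must be <= alpha, got ({alpha}, {beta})")
    basis = pzm_basis(alpha, beta, image.x, image.y, cache)
    total = np.sum(image.values * np.conj(basis)) * image.pixel_area
    return complex((alpha + 1) / math.pi * total)


def basis_matrix(
    pairs: list[tuple[int, int]], x: np.ndarray, y: np.ndarray,
    cache: PzmBasisCache | None = None,
) -> np.ndarray:
    """Stack V_ab over cells: shape (len(pairs), len(x)) complex array."""
    cache = cache or PzmBasisCache()
    return np.stack([pzm_basis(a, b, x, y, cache) for a, b in pairs])


def pzm_feature_vector(
    pssm: Pssm, alpha_max: int = 10, cache: PzmBasisCache | None = None
) -> PzmFeatureVector:
    """Full protein descriptor: logistic-normalize, inscribe, take |M_ab|.

    Negative repetitions are omitted because |M_{a,-b}| = |M_{a,b}|; the
    default order bound 10 yields 65 features. Powers of rho and the
    angular phases are shared across all (a, b) pairs, so the cost is
    linear in grid size.
    """
    if alpha_max < 1:
        raise ValueError("alpha_max must be >= 1")
    cache = cache or PzmBasisCache()
    image = to_unit_disk(normalize_pssm(pssm))
    rho = np.hypot(image.x, image.y)
    theta = np.arctan2(image.y, image.x)

    # rho^d for d = 0..alpha_max and exp(-j*b*theta) for b = 0..alpha_max
    powers = np.empty((alpha_max + 1, rho.size))
    powers[0] = 1.0
    for d in range(1, alpha_max + 1):
        powers[d] = powers[d - 1] * rho
    phases = np.empty((alpha_max + 1, rho.size), dtype=complex)
    phases[0] = 1.0
    step = np.exp(-1j * theta)
    for b in range(1, alpha_max + 1):
        phases[b] = phases[b - 1] * step

    weighted = image.values * image.pixel_area
    mags = []
    for alpha, beta in moment_pairs(alpha_max):
        coeffs = cache.radial_coefficients(alpha, beta)
        degrees = alpha - np.arange(coeffs.size)
        radial = coeffs @ powers[degrees]
        moment = (alpha + 1) / math.pi * np.sum(weighted * radial * phases[beta])
        mags.append(abs(moment))
    return PzmFeatureVector(np.array(mags), alpha_max)
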