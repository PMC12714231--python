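"""Synthetic imaging, count-table, and peptide generators.

The generators emulate the structure of the study's inputs so every
downstream stage is testable without any microscope or mass-spectrometry
data:

* two-channel 2-D images of blob-like cells scattered along a (possibly
  curved) gut midline, with controllable touching-cell clusters,
  per-channel amplitudes, background and Gaussian noise, and a ground
  truth table of every cell;
* per-fish long-format count tables with negative-binomial (or Poisson)
  noise and a multiplicative ablation effect per subtype and gut
  quarter, able to emulate the 30-50% reductions seen in ablation
  experiments;
* peptide lists tiling a prohormone precursor with termini preferring
  dibasic cleavage sites and modifications from the peptidomics search
  set.

Every generator is a pure function of its spec including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from eecquant.atlas import MODIFICATION_MASS, PeptideHit, Precursor

GROUPS = ("control", "ablated")

#: Center-to-center spacing factor for touching cells within a cluster;
#: at 1.2 x radius the rendered blobs merge into one connected component
#: at any threshold low enough to capture most of each blob.
CLUSTER_SPACING = 1.2


@dataclass
class SimCell:
    """One simulated cell.

    ``axial_fraction`` places the cell along the gut midline by
    arc length; ``cluster_id`` groups cells that must be rendered
    touching (-1 for singletons); ``true_class`` is the ground-truth
    dual-reporter label.
    """

    axial_fraction: float
    radius: float
    channel_amplitudes: tuple[float, ...]
    cluster_id: int = -1
    true_class: str = "A-only"
    center: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.axial_fraction <= 1.0:
            raise ValueError("axial_fraction outside [0, 1]")
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if any(a < 0 for a in self.channel_amplitudes):
            raise ValueError("negative channel amplitude")


@dataclass
class SimImageSpec:
    """Specification of one synthetic gut image.

    ``gut_path`` is an ordered polyline of (row, col) control points for
    the midline; ``gut_start``/``gut_end`` default to its endpoints and
    stand for the manually placed markers.  ``psf_sigma`` is a final
    isotropic optical blur in pixels.
    """

    image_shape: tuple[int, int]
    n_channels: int = 1
    gut_path: np.ndarray | None = None
    gut_start: tuple[float, float] | None = None
    gut_end: tuple[float, float] | None = None
    cells: list[SimCell] = field(default_factory=list)
    background_level: float = 0.0
    noise_sd: float = 0.0
    psf_sigma: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        rows, cols = self.image_shape
        if rows <= 0 or cols <= 0:
            raise ValueError("image_shape must be positive")
        if self.background_level < 0 or self.noise_sd < 0:
            raise ValueError("background_level and noise_sd must be >= 0")
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be positive")
        if self.gut_path is None:
            self.gut_path = straight_gut_path(self.image_shape)
        self.gut_path = np.asarray(self.gut_path, dtype=float)
        if self.gut_start is None:
            self.gut_start = tuple(self.gut_path[0])
        if self.gut_end is None:
            self.gut_end = tuple(self.gut_path[-1])
        if tuple(self.gut_start) == tuple(self.gut_end):
            raise ValueError("gut_start must differ from gut_end")
        for cell in self.cells:
            if len(cell.channel_amplitudes) != self.n_channels:
                raise ValueError(
                    "cell channel_amplitudes length does not match n_channels"
                )


def straight_gut_path(
    image_shape: tuple[int, int], margin: float = 60.0
) -> np.ndarray:
    """Horizontal midline through the image center, margin px from edges."""
    rows, cols = image_shape
    return np.array([[rows / 2.0, margin], [rows / 2.0, cols - margin]])


def sine_gut_path(
    image_shape: tuple[int, int],
    amplitude: float = 140.0,
    periods: float = 2.0,
    margin: float = 60.0,
    n_points: int = 400,
) -> np.ndarray:
    """A sinuous midline emulating the folded larval gut."""
    rows, cols = image_shape
    x = np.linspace(margin, cols - margin, n_points)
    y = rows / 2.0 + amplitude * np.sin(2 * np.pi * periods * (x - x[0]) / (x[-1] - x[0]))
    return np.column_stack([y, x])


def path_point(path: np.ndarray, fraction: float) -> tuple[np.ndarray, np.ndarray]:
    """Point at an arc-length fraction along a polyline, plus unit tangent."""
    path = np.asarray(path, dtype=float)
    seg = np.diff(path, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    target = fraction * cum[-1]
    i = min(int(np.searchsorted(cum, target, side="right")) - 1, len(seg) - 1)
    i = max(i, 0)
    t = (target - cum[i]) / seg_len[i] if seg_len[i] > 0 else 0.0
    point = path[i] + t * seg[i]
    tangent = seg[i] / seg_len[i]
    return point, tangent


def scatter_cells(
    cluster_sizes: list[int],
    radius: float = 4.0,
    channel_amplitudes: tuple[float, ...] = (1000.0,),
    true_class: str = "A-only",
    margin_fraction: float = 0.03,
) -> list[SimCell]:
    """Cells at evenly spaced axial fractions; entries > 1 become clusters.

    ``cluster_sizes=[1]*100`` yields 100 well-separated singletons;
    ``[1]*6 + [2, 3]`` yields six singletons plus a touching pair and a
    touching triple, the canonical exercise of the median-area weighting
    rule.
    """
    k = len(cluster_sizes)
    fractions = margin_fraction + (1 - 2 * margin_fraction) * (np.arange(k) + 0.5) / k
    cells = []
    for cid, (size, frac) in enumerate(zip(cluster_sizes, fractions)):
        for _ in range(size):
            cells.append(
                SimCell(
                    axial_fraction=float(frac),
                    radius=radius,
                    channel_amplitudes=channel_amplitudes,
                    cluster_id=cid if size > 1 else -1,
                    true_class=true_class,
                )
            )
    return cells


def _resolve_centers(spec: SimImageSpec, rng: np.random.Generator) -> np.ndarray:
    """Place cells on the gut path; cluster members chain along the tangent.

    The anchor of each cluster (and every singleton) is jittered
    perpendicular to the path by at most one radius; members share the
    anchor's jitter so intra-cluster geometry stays exact.
    """
    centers = np.zeros((len(spec.cells), 2))
    anchors: dict[int, tuple[np.ndarray, np.ndarray, int]] = {}
    for i, cell in enumerate(spec.cells):
        if cell.center is not None:
            centers[i] = cell.center
            continue
        key = cell.cluster_id
        if key < 0 or key not in anchors:
            point, tangent = path_point(spec.gut_path, cell.axial_fraction)
            normal = np.array([-tangent[1], tangent[0]])
            offset = rng.uniform(-1.0, 1.0) * cell.radius
            anchor = point + offset * normal
            member = 0
            if key >= 0:
                anchors[key] = (anchor, tangent, 0)
        else:
            anchor, tangent, member = anchors[key]
            member += 1
            anchors[key] = (anchor, tangent, member)
        centers[i] = anchor + member * CLUSTER_SPACING * cell.radius * tangent
    return centers


def render_image(spec: SimImageSpec) -> tuple[np.ndarray, pd.DataFrame]:
    """Render the spec into an intensity stack plus its ground-truth table.

    Each cell is a Gaussian disc — amplitude x exp(-d^2 / 2 sigma^2) with
    sigma = radius / 3, truncated at 3 sigma (= the radius) — summed into
    every channel at its amplitude, followed by an isotropic
    ``psf_sigma`` blur, additive background, and Gaussian noise clipped
    at zero.  Identical specs (including seed) give bit-identical
    output.

    Returns
    -------
    stack : ndarray, (n_channels, rows, cols)
    truth : DataFrame
        Columns cell_id, row, col, axial_fraction, true_class,
        cluster_id — one row per simulated cell.
    """
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.image_shape
    stack = np.zeros((spec.n_channels, rows, cols))
    centers = _resolve_centers(spec, rng)

    for i, cell in enumerate(spec.cells):
        r0, c0 = centers[i]
        if not (0 <= r0 < rows and 0 <= c0 < cols):
            raise ValueError(
                f"cell {i} center ({r0:.1f}, {c0:.1f}) outside image {spec.image_shape}"
            )
        rad = cell.radius
        rlo, rhi = int(np.floor(r0 - rad)), int(np.ceil(r0 + rad)) + 1
        clo, chi = int(np.floor(c0 - rad)), int(np.ceil(c0 + rad)) + 1
        rlo, clo = max(rlo, 0), max(clo, 0)
        rhi, chi = min(rhi, rows), min(chi, cols)
        rr, cc = np.meshgrid(np.arange(rlo, rhi), np.arange(clo, chi), indexing="ij")
        d2 = (rr - r0) ** 2 + (cc - c0) ** 2
        sigma = rad / 3.0
        profile = np.exp(-d2 / (2.0 * sigma**2))
        profile[d2 > rad**2] = 0.0
        for ch in range(spec.n_channels):
            stack[ch, rlo:rhi, clo:chi] += cell.channel_amplitudes[ch] * profile

    for ch in range(spec.n_channels):
        stack[ch] = gaussian_filter(stack[ch], sigma=spec.psf_sigma)
    stack += spec.background_level
    if spec.noise_sd > 0:
        stack += rng.normal(0.0, spec.noise_sd, size=stack.shape)
        np.clip(stack, 0.0, None, out=stack)

    truth = pd.DataFrame(
        {
            "cell_id": np.arange(len(spec.cells)),
            "row": centers[:, 0],
            "col": centers[:, 1],
            "axial_fraction": [c.axial_fraction for c in spec.cells],
            "true_class": [c.true_class for c in spec.cells],
            "cluster_id": [c.cluster_id for c in spec.cells],
        }
    )
    return stack, truth


@dataclass
class SimCohortSpec:
    """Specification of a two-group (control vs ablated) count cohort.

    ``group_means`` maps subtype -> expected cells per fish per quarter
    (a scalar applies to all four quarters); ``effect`` is the
    multiplicative reduction in the ablated group, per subtype (scalar or
    per-quarter), in [0, 1] — e.g. 0.5 for the ~50% total EEC loss and
    0.3 for the ~30% subtype reductions seen after progenitor ablation.
    ``dispersion`` is the negative-binomial overdispersion alpha in
    Var = mu + alpha mu^2; 0 gives Poisson counts.
    """

    n_fish_per_group: int
    group_means: dict[str, float | tuple[float, float, float, float]]
    effect: dict[str, float | tuple[float, float, float, float]] | float = 0.0
    dispersion: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fish_per_group < 2:
            raise ValueError("n_fish_per_group must be >= 2")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        self._means = {
            sub: _per_quarter(v, "group_means") for sub, v in self.group_means.items()
        }
        if not isinstance(self.effect, dict):
            eff = {sub: self.effect for sub in self.group_means}
        else:
            eff = dict(self.effect)
        self._effect = {
            sub: _per_quarter(eff.get(sub, 0.0), "effect") for sub in self.group_means
        }
        for sub, quarters in self._means.items():
            if any(m < 0 for m in quarters):
                raise ValueError(f"negative mean for subtype {sub!r}")
        for sub, quarters in self._effect.items():
            if any(not 0 <= e <= 1 for e in quarters):
                raise ValueError(f"effect outside [0, 1] for subtype {sub!r}")


def _per_quarter(value, name: str) -> tuple[float, float, float, float]:
    arr = np.atleast_1d(np.asarray(value, dtype=float))
    if arr.size == 1:
        return tuple(float(arr[0]) for _ in range(4))
    if arr.size != 4:
        raise ValueError(f"{name} entries must be scalar or length 4")
    return tuple(float(v) for v in arr)


def simulate_counts(spec: SimCohortSpec) -> pd.DataFrame:
    """Draw a long-format per-fish count table.

    One row per fish x subtype x quarter with a non-negative integer
    count from NB(mean = group_mean x (1 - effect) for ablated fish,
    dispersion alpha), reducing to Poisson at alpha = 0.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for group in GROUPS:
        for fish in range(spec.n_fish_per_group):
            fish_id = f"{group}_{fish:03d}"
            for subtype, quarter_means in spec._means.items():
                for q in range(4):
                    mu = quarter_means[q]
                    if group == "ablated":
                        mu *= 1.0 - spec._effect[subtype][q]
                    rows.append(
                        (fish_id, group, subtype, q + 1, _draw_count(rng, mu, spec.dispersion))
                    )
    return pd.DataFrame(rows, columns=["fish_id", "group", "subtype", "quarter", "count"])


def _draw_count(rng: np.random.Generator, mu: float, alpha: float) -> int:
    if mu <= 0:
        return 0
    if alpha <= 1e-12:
        return int(rng.poisson(mu))
    n = 1.0 / alpha
    p = n / (n + mu)
    return int(rng.negative_binomial(n, p))


def cleavage_fragments(precursor: Precursor | str) -> list[tuple[int, int]]:
    """(start, end) spans between basic-residue cleavage blocks, 1-based.

    Maximal runs of two or more K/R residues act as prohormone-convertase
    cleavage blocks; the excised blocks separate the precursor into the
    fragments a fully processed peptidome would contain.
    """
    seq = precursor.sequence if isinstance(precursor, Precursor) else precursor
    frags = []
    start = 1
    i = 0
    while i < len(seq):
        if seq[i] in "KR":
            j = i
            while j < len(seq) and seq[j] in "KR":
                j += 1
            if j - i >= 2:  # cleavage block
                if i >= start:
                    frags.append((start, i))  # end just before the block
                start = j + 1
            i = j
        else:
            i += 1
    if start <= len(seq):
        frags.append((start, len(seq)))
    return [(s, e) for s, e in frags if e >= s]


def simulate_peptides(
    precursor: Precursor,
    n_peptides: int,
    seed: int = 0,
    dibasic_preference: float = 0.75,
    min_length: int = 4,
    max_length: int = 40,
) -> list[PeptideHit]:
    """Sample peptides tiling a precursor with prohormone-like termini.

    With probability ``dibasic_preference`` a peptide is an exact
    cleavage-bounded fragment (termini adjacent to a dibasic KK/KR/RK/RR
    block or at the precursor's own ends); otherwise its termini are
    uniform, emulating ragged degradation products.  Modifications are
    sampled from the peptidomics search set (carbamidomethyl fixed on
    Cys; oxidation, C-terminal amidation, N-terminal pyroglutamate
    variable).  Every returned hit records its true (start, end)
    alignment.
    """
    if len(precursor) < 10:
        raise ValueError("precursor must be at least 10 residues")
    rng = np.random.default_rng(seed)
    L = len(precursor)
    frags = [
        (s, e)
        for s, e in cleavage_fragments(precursor)
        if min_length <= e - s + 1 <= max_length
    ]

    hits: list[PeptideHit] = []
    for _ in range(n_peptides):
        if frags and rng.random() < dibasic_preference:
            start, end = frags[int(rng.integers(len(frags)))]
        else:
            start, end = _draw_uniform_termini(rng, L, min_length, max_length)
        seq = precursor.sequence[start - 1 : end]
        mods: list[tuple[int, str, float]] = []
        for pos, aa in enumerate(seq, start=1):
            if aa == "C":
                mods.append((pos, "carbamidomethyl", MODIFICATION_MASS["carbamidomethyl"]))
            elif aa == "M" and rng.random() < 0.2:
                mods.append((pos, "oxidation", MODIFICATION_MASS["oxidation"]))
        if seq[0] == "Q" and rng.random() < 0.3:
            mods.append((1, "pyroglutamate-from-Q", MODIFICATION_MASS["pyroglutamate-from-Q"]))
        elif seq[0] == "E" and rng.random() < 0.3:
            mods.append((1, "pyroglutamate-from-E", MODIFICATION_MASS["pyroglutamate-from-E"]))
        if rng.random() < 0.15:
            mods.append((len(seq), "amidation", MODIFICATION_MASS["amidation"]))
        hits.append(
            PeptideHit(
                sequence=seq,
                modifications=mods,
                precursor_id=precursor.id,
                alignment=(start, end),
            )
        )
    return hits


def _draw_uniform_termini(rng, L, min_length, max_length) -> tuple[int, int]:
    for _ in range(200):
        start = int(rng.integers(1, L + 1))
        end = int(rng.integers(1, L + 1))
        if start <= end and min_length <= end - start + 1 <= max_length:
            return start, end
    # degenerate precursors: fall back to a minimal window
    start = int(rng.integers(1, max(2, L - min_length + 2)))
    end = min(L, start + min_length - 1)
    return start, end
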