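"""Ground-truthed synthetic inputs for the imaging and cohort pipelines.

Two generators and a fixture loader:

* :func:`generate_vm_image` renders a branching bright tubular network
  (basement-membrane channel) and a partially overlapping vessel network
  (endothelial channel) over a noisy tissue background, returning the exact
  masks and the true mimicry area fraction.
* :func:`generate_expression_cohort` draws a negative-binomial count matrix
  with a planted keratinocyte-contaminated subset, a heterogeneous
  stratification-gene gradient, planted differentially expressed genes and
  exponential survival with a group-dependent hazard.
* :func:`load_paper_fixtures` returns the transcribed matched primary/
  metastasis status table, autopsy counts and the stage contingency table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .expression import CountMatrix
from .vm_imaging import TwoChannelImage

__all__ = [
    "SyntheticImageSpec",
    "GroundTruthImage",
    "SyntheticCohortSpec",
    "CohortTruth",
    "MatchedRow",
    "PaperFixtures",
    "generate_vm_image",
    "generate_expression_cohort",
    "load_paper_fixtures",
]


# --------------------------------------------------------------------------
# images
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticImageSpec:
    width_px: int = 256
    height_px: int = 256
    n_branches: int = 12
    tube_width_px: float = 2.5
    network_intensity: float = 1.0
    vessel_intensity: float = 1.0
    background_level: float = 0.15
    noise_sd: float = 0.02
    vessel_overlap_fraction: float = 0.3
    tissue_fraction: float = 1.0
    n_vessel_branches: int = 6
    segment_length_px: tuple[float, float] = (25.0, 55.0)
    branch_angle_jitter_rad: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_px < 64 or self.height_px < 64:
            raise ValueError("width_px and height_px must be >= 64")
        if self.tube_width_px < 1:
            raise ValueError("tube_width_px must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.vessel_overlap_fraction <= 1:
            raise ValueError("vessel_overlap_fraction must lie in [0, 1]")
        if not 0 < self.tissue_fraction <= 1:
            raise ValueError(
                "tissue_fraction must lie in (0, 1]; zero tissue is degenerate"
            )
        if self.n_branches < 0 or self.n_vessel_branches < 0:
            raise ValueError("branch counts must be >= 0")
        for name in (
            "network_intensity",
            "vessel_intensity",
            "background_level",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class GroundTruthImage:
    image: TwoChannelImage
    true_network_mask: np.ndarray
    true_vessel_mask: np.ndarray
    true_tissue_mask: np.ndarray
    true_vm_area_fraction: float
    spec: SyntheticImageSpec | None = None


def _tissue_mask(spec: SyntheticImageSpec) -> np.ndarray:
    h, w = spec.height_px, spec.width_px
    if spec.tissue_fraction >= 1.0:
        return np.ones((h, w), dtype=bool)
    rr, cc = np.mgrid[0:h, 0:w]
    radius = np.sqrt(spec.tissue_fraction * h * w / np.pi)
    return (rr - h / 2) ** 2 + (cc - w / 2) ** 2 <= radius**2


def _grow_tree(
    rng: np.random.Generator,
    n_segments: int,
    tissue: np.ndarray,
    spec: SyntheticImageSpec,
) -> list[np.ndarray]:
    """Random recursive branching walk; each segment is an (n, 2) array of
    row/col centerline pixels clipped to the tissue."""
    if n_segments == 0:
        return []
    h, w = tissue.shape
    in_rows, in_cols = np.nonzero(tissue)
    segments: list[np.ndarray] = []
    # roots are seeded until the branch budget is exhausted
    stack: list[tuple[float, float, float]] = []
    lo, hi = spec.segment_length_px
    while len(segments) < n_segments:
        if not stack:
            j = rng.integers(len(in_rows))
            stack.append(
                (float(in_rows[j]), float(in_cols[j]), rng.uniform(0, 2 * np.pi))
            )
        r, c, ang = stack.pop()
        length = rng.uniform(lo, hi)
        n_steps = max(2, int(np.ceil(length)))
        t = np.linspace(0, length, n_steps)
        rows = np.clip(np.rint(r + t * np.sin(ang)).astype(int), 0, h - 1)
        cols = np.clip(np.rint(c + t * np.cos(ang)).astype(int), 0, w - 1)
        keep = tissue[rows, cols]
        pts = np.column_stack([rows[keep], cols[keep]])
        if len(pts) >= 2:
            segments.append(pts)
            end_r, end_c = float(rows[-1]), float(cols[-1])
            for sign in (-1.0, 1.0):
                child = ang + sign * abs(rng.normal(0, spec.branch_angle_jitter_rad))
                stack.append((end_r, end_c, child))
            rng.shuffle(stack)
    return segments[:n_segments]


def _render_tubes(
    segments: Sequence[np.ndarray], shape: tuple[int, int], tube_width: float
) -> tuple[np.ndarray, np.ndarray]:
    """Render centerline segments as unit-amplitude Gaussian-profile tubes.

    Returns (intensity in [0, 1], truth mask = pixels within one tube width
    of a centerline).
    """
    canvas = np.zeros(shape, dtype=bool)
    for seg in segments:
        canvas[seg[:, 0], seg[:, 1]] = True
    if not canvas.any():
        return np.zeros(shape), np.zeros(shape, dtype=bool)
    dist = ndimage.distance_transform_edt(~canvas)
    intensity = np.exp(-(dist**2) / (2 * tube_width**2))
    return intensity, dist <= tube_width


def generate_vm_image(spec: SyntheticImageSpec) -> GroundTruthImage:
    """Render a two-channel synthetic tissue with known mimicry fraction.

    A seeded run is a pure function of the spec: identical specs give
    bit-identical rasters. A ``vessel_overlap_fraction`` of the vessel
    segments re-uses network centerlines (co-staining); at 1.0 the vessels
    cover the entire network and the true mimicry fraction is exactly 0.
    """
    rng = np.random.default_rng(spec.seed)
    tissue = _tissue_mask(spec)
    shape = (spec.height_px, spec.width_px)

    net_segments = _grow_tree(rng, spec.n_branches, tissue, spec)

    if spec.vessel_overlap_fraction >= 1.0:
        vessel_segments = list(net_segments)
    else:
        n_overlap = int(round(spec.vessel_overlap_fraction * spec.n_vessel_branches))
        n_overlap = min(n_overlap, len(net_segments))
        chosen = (
            list(rng.choice(len(net_segments), size=n_overlap, replace=False))
            if n_overlap
            else []
        )
        own = _grow_tree(rng, spec.n_vessel_branches - n_overlap, tissue, spec)
        vessel_segments = [net_segments[i] for i in chosen] + own

    net_profile, net_mask = _render_tubes(net_segments, shape, spec.tube_width_px)
    ves_profile, ves_mask = _render_tubes(vessel_segments, shape, spec.tube_width_px)

    pas = spec.background_level * tissue + spec.network_intensity * net_profile * tissue
    cd31 = (
        0.5 * spec.background_level * tissue
        + spec.vessel_intensity * ves_profile * tissue
    )
    if spec.noise_sd > 0:
        pas = pas + rng.normal(0, spec.noise_sd, shape)
        cd31 = cd31 + rng.normal(0, spec.noise_sd, shape)
    pas = np.clip(pas, 0, None)
    cd31 = np.clip(cd31, 0, None)

    net_mask &= tissue
    ves_mask &= tissue
    vm = net_mask & ~ves_mask & tissue
    frac = float(vm.sum() / tissue.sum())

    return GroundTruthImage(
        image=TwoChannelImage(pas=pas, cd31=cd31, tissue_mask=None),
        true_network_mask=net_mask,
        true_vessel_mask=ves_mask,
        true_tissue_mask=tissue,
        true_vm_area_fraction=frac,
        spec=spec,
    )


# --------------------------------------------------------------------------
# cohorts
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticCohortSpec:
    n_samples: int = 200
    n_genes: int = 1000
    n_contaminated: int = 20
    marker_gene_ids: tuple[str, str, str] = ("IVL", "KRT14", "BNC1")
    contaminated_marker_cpm_range: tuple[float, float] = (30.0, 300.0)
    clean_marker_cpm_max: float = 2.0
    dsg2_gene_id: str = "DSG2"
    dsg2_range: tuple[float, float] = (5.0, 500.0)
    n_de_genes: int = 50
    de_log2fc: float = 2.0
    nb_dispersion: float = 0.1
    library_size_mean: int = 1_000_000
    true_hazard_ratio: float = 2.6
    baseline_hazard_per_day: float = 1.0 / 2000.0
    censoring_rate_per_day: float = 1.0 / 8000.0
    admin_censor_days: float = 10_000.0
    strat_fraction: float = 0.10
    dsg2_gap: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_contaminated > self.n_samples:
            raise ValueError("n_contaminated must be <= n_samples")
        if self.n_de_genes > self.n_genes:
            raise ValueError("n_de_genes must be <= n_genes")
        if self.true_hazard_ratio <= 0:
            raise ValueError("true_hazard_ratio must be > 0")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        lo, hi = self.contaminated_marker_cpm_range
        if lo >= hi:
            raise ValueError("contaminated_marker_cpm_range must be increasing")
        if lo <= self.clean_marker_cpm_max:
            raise ValueError(
                "contaminated marker range must lie above clean_marker_cpm_max; "
                "otherwise the planted contamination truth is ill-defined"
            )
        if len(self.marker_gene_ids) != 3:
            raise ValueError("exactly three marker genes required")
        if not 0 < self.strat_fraction < 0.5:
            raise ValueError("strat_fraction must lie in (0, 0.5)")


@dataclass
class CohortTruth:
    contaminated_sample_ids: set
    de_gene_ids: set
    group_of_sample: dict
    true_hazard_ratio: float


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """NB(mean, dispersion phi) via gamma-Poisson mixture; phi=0 is Poisson."""
    mean = np.clip(mean, 1e-12, None)
    if phi <= 0:
        return rng.poisson(mean)
    shape = 1.0 / phi
    return rng.poisson(rng.gamma(shape, mean * phi))


def _planted_dsg2(
    rng: np.random.Generator, spec: SyntheticCohortSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample stratification-gene CPM plus planted group labels.

    With ``dsg2_gap`` the three groups occupy separated bands so that
    range-mode cuts at ``strat_fraction`` fall inside the gaps and the
    planted labels are exactly recoverable downstream.
    """
    r0, r1 = spec.dsg2_range
    span = r1 - r0
    f = spec.strat_fraction
    n = spec.n_samples
    n_low = max(1, int(round(f * n)))
    n_high = max(1, int(round(f * n)))
    labels = np.array(
        ["low"] * n_low + ["high"] * n_high + ["mid"] * (n - n_low - n_high)
    )
    rng.shuffle(labels)
    values = np.empty(n)
    low_band = (r0, r0 + 0.5 * f * span)
    high_band = (r1 - 0.5 * f * span, r1)
    mid_band = (r0 + 2 * f * span, r1 - 2 * f * span)
    if not spec.dsg2_gap:
        values = rng.uniform(r0, r1, n)
        # labels follow the realized range cuts on the planted values
        lo_cut = values.min() + f * (values.max() - values.min())
        hi_cut = values.max() - f * (values.max() - values.min())
        labels = np.where(values < lo_cut, "low", np.where(values > hi_cut, "high", "mid"))
        return values, labels
    for band, name in ((low_band, "low"), (high_band, "high"), (mid_band, "mid")):
        idx = labels == name
        values[idx] = rng.uniform(band[0], band[1], idx.sum())
    # pin the extremes so the realized range matches the nominal one
    values[np.argmin(values)] = r0
    values[np.argmax(values)] = r1
    return values, labels


def generate_expression_cohort(
    spec: SyntheticCohortSpec,
) -> tuple[CountMatrix, pd.DataFrame, CohortTruth]:
    """Draw a seeded cohort: counts, clinical table, and the planted truth.

    Ordinary genes are negative-binomial around lognormal base abundances.
    The stratification gene and the three contamination markers are planted
    deterministically from their target CPM (rounded expected counts), so
    the planted labels survive count noise. Planted DE genes have their
    mean multiplied by ``2**de_log2fc`` in the high group.
    """
    rng = np.random.default_rng(spec.seed)
    n, g = spec.n_samples, spec.n_genes
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    special = (*spec.marker_gene_ids, spec.dsg2_gene_id)
    n_ordinary = g - len(special)
    if n_ordinary < spec.n_de_genes:
        raise ValueError("n_genes too small for requested n_de_genes")
    gene_ids = list(special) + [f"G{i + 1:05d}" for i in range(n_ordinary)]

    lib = rng.lognormal(np.log(spec.library_size_mean), 0.15, n)

    contaminated = set(
        rng.choice(sample_ids, size=spec.n_contaminated, replace=False).tolist()
    )
    is_cont = np.array([s in contaminated for s in sample_ids])

    # markers: shared latent contamination level -> correlated triple
    lo, hi = spec.contaminated_marker_cpm_range
    marker_cpm = np.empty((3, n))
    clean = rng.uniform(0, spec.clean_marker_cpm_max, (3, n))
    latent = rng.uniform(lo, hi, n)
    jitter = np.exp(rng.normal(0, 0.08, (3, n)))
    cont = np.clip(latent * jitter, lo, hi)
    marker_cpm[:, :] = np.where(is_cont, cont, clean)

    dsg2_cpm, labels = _planted_dsg2(rng, spec)
    groups = dict(zip(sample_ids, labels.tolist()))
    is_high = labels == "high"

    base_cpm = rng.lognormal(3.0, 1.2, n_ordinary)
    de_idx = rng.choice(n_ordinary, size=spec.n_de_genes, replace=False)
    de_gene_ids = {gene_ids[len(special) + i] for i in de_idx}

    mean_cpm = np.tile(base_cpm[:, None], (1, n))
    mean_cpm[de_idx[:, None], np.nonzero(is_high)[0][None, :]] *= 2.0**spec.de_log2fc
    # rescale so every sample's expected CPM column sums to 1e6, keeping the
    # planted marker / stratification-gene CPM values exact
    special_cpm = marker_cpm.sum(axis=0) + dsg2_cpm
    mean_cpm *= (1e6 - special_cpm) / mean_cpm.sum(axis=0)

    counts = np.empty((g, n))
    counts[len(special):] = _nb_draw(rng, mean_cpm / 1e6 * lib, spec.nb_dispersion)
    # solve for the planted genes' counts against the realized totals so the
    # realized CPM of markers and the stratification gene equals the planted
    # value exactly (up to count rounding): c_i / (T_other + sum c) = p_i/1e6
    special_cpm_mat = np.vstack([marker_cpm, dsg2_cpm[None, :]])
    p_sum = special_cpm_mat.sum(axis=0)
    t_other = counts[len(special):].sum(axis=0)
    counts[: len(special)] = np.rint(
        special_cpm_mat / (1e6 - p_sum) * t_other
    )

    matrix = CountMatrix(gene_ids, sample_ids, counts)

    hazard = spec.baseline_hazard_per_day * np.where(
        is_high, spec.true_hazard_ratio, 1.0
    )
    death = rng.exponential(1.0 / hazard)
    if spec.censoring_rate_per_day > 0:
        censor = rng.exponential(1.0 / spec.censoring_rate_per_day, n)
    else:
        censor = np.full(n, np.inf)
    censor = np.minimum(censor, spec.admin_censor_days)
    days = np.minimum(death, censor)
    event = death <= censor

    stages = rng.choice(["II", "III", "IV"], size=n, p=[0.5, 0.3, 0.2])
    amp_p = np.where(is_high, 0.3, 0.08)
    clinical = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "days": np.round(days, 1),
            "event": event.astype(int),
            "stage": stages,
            "dsg2_cnv_amplified": (rng.uniform(size=n) < amp_p).astype(int),
        }
    )

    truth = CohortTruth(
        contaminated_sample_ids=contaminated,
        de_gene_ids=de_gene_ids,
        group_of_sample=groups,
        true_hazard_ratio=spec.true_hazard_ratio,
    )
    return matrix, clinical, truth


# --------------------------------------------------------------------------
# transcribed fixture tables
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class MatchedRow:
    patient_id: int
    primary_status: str
    metastasis_status: str
    metastasis_site: str


@dataclass
class PaperFixtures:
    matched_cohort_table: list[MatchedRow]
    autopsy_counts: pd.DataFrame
    stage_contingency: np.ndarray = field(
        default_factory=lambda: np.zeros((2, 2), dtype=int)
    )


def load_paper_fixtures() -> PaperFixtures:
    """Transcribed in-study tables used by the acceptance checks.

    The stage contingency is reconstructed from the printed summary
    percentages: 39% of 46 primary tumors positive (0.39 x 46 = 17.94 -> 18,
    so 28 negative) and 24% of 25 metastatic tumors positive
    (0.24 x 25 = 6, so 19 negative).
    """
    matched = [
        MatchedRow(1, "-", "-", "lymph node"),
        MatchedRow(2, "-", "-", "lymph node"),
        MatchedRow(3, "-", "+", "dermis"),
        MatchedRow(4, "+", "+", "lung"),
        MatchedRow(5, "+", "-", "lymph node"),
        MatchedRow(6, "+", "+", "lymph node"),
        MatchedRow(7, "+", "+", "soft tissue"),
        MatchedRow(8, "+", "+", "lymph node"),
    ]
    autopsy = pd.DataFrame(
        {
            "patient_id": ["autopsy_1", "autopsy_2", "autopsy_3"],
            "n_positive": [6, 5, 2],
            "n_total": [6, 6, 5],
        }
    )
    contingency = np.array([[18, 28], [6, 19]], dtype=int)
    return PaperFixtures(
        matched_cohort_table=matched,
        autopsy_counts=autopsy,
        stage_contingency=contingency,
    )
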