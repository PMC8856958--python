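"""Synthetic-data generators: transcriptome fixtures with planted
off-target runs, striatal co-expression cell tables, and rendered
two-channel images with ground-truth masks.

The cell-table generator emulates the statistical structure the analyses
assume: regions with 8-15 marker-positive cells/mm^2, a ~30/60/10
strong/medium/weak baseline category mix, ~80% penetrance of the viral
reporter, an inverse-linear knockdown of marker intensity with reporter
dose (slope ``beta``), and a small linear leakage ``leakage`` of the
marker signal into the reporter channel.  Everything is driven by a
single integer seed; a fixed seed gives byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from skimage import draw

from .imaging import CellMask, ChannelImage
from .sequences import NucSequence, Transcriptome

__all__ = [
    "TxomeSpec",
    "CoexprSpec",
    "RecoveryResult",
    "make_transcriptome",
    "simulate_cell_table",
    "render_images",
    "recover_parameters",
]

_ALPHABET = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_ALPHABET, size=n).tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# transcriptome fixtures

@dataclass(frozen=True)
class TxomeSpec:
    """Recipe for a background transcriptome with a multi-isoform target.

    ``planted_runs`` is a sequence of ``(candidate_start, run_length)``
    pairs: for each, a ``run_length``-nt exact copy of (part of) the
    22-nt pre-mismatch window at that candidate start on the reference
    isoform is planted into one decoy transcript, with mismatching bases
    forced at both flanks so the true maximal shared run equals
    ``run_length``.
    """

    n_decoys: int = 50
    decoy_length: int = 500
    target_cds: str | None = None
    cds_length: int = 600
    n_isoforms: int = 4
    utr_length: int = 50
    planted_runs: tuple[tuple[int, int], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        for start, k in self.planted_runs:
            if not (1 <= k <= 22):
                raise ValueError(f"planted run length {k} outside [1, 22]")
            if start < 2:
                raise ValueError("planted run start must be an admissible candidate start (>= 2)")


def make_transcriptome(spec: TxomeSpec) -> tuple[Transcriptome, dict]:
    """Generate a transcriptome fixture plus a truth record.

    All isoforms contain the shared CDS verbatim (they differ in random
    UTRs; the first isoform is the longest and thus the design pipeline's
    reference).  Decoys are random except for the planted runs.  The
    truth record lists, per planted run, the decoy it went into and its
    exact length.
    """
    rng = np.random.default_rng(spec.seed)
    cds = spec.target_cds or _random_dna(rng, spec.cds_length)
    isoforms = []
    for i in range(spec.n_isoforms):
        # descending UTR lengths make isoform 1 the longest
        u5 = spec.utr_length + (spec.n_isoforms - i) * 10
        u3 = spec.utr_length + (spec.n_isoforms - i) * 10
        seq = _random_dna(rng, u5) + cds + _random_dna(rng, u3)
        isoforms.append(NucSequence(f"target_iso{i + 1}", seq))
    reference = isoforms[0]

    decoys = [bytearray(_random_dna(rng, spec.decoy_length), "ascii") for _ in range(spec.n_decoys)]
    planted = []
    others = "ACGT"
    for j, (start, k) in enumerate(spec.planted_runs):
        window = reference.seq[start - 2 : start + 20]
        if len(window) != 22:
            raise ValueError(f"candidate start {start} has no full 22-nt window")
        offset = (22 - k) // 2
        run = window[offset : offset + k]
        d = j % spec.n_decoys
        pos = int(rng.integers(1, spec.decoy_length - k - 1))
        decoys[d][pos : pos + k] = run.encode("ascii")
        # force flanking mismatches so the shared run cannot extend
        if offset > 0:
            left = window[offset - 1]
            decoys[d][pos - 1] = ord(rng.choice([c for c in others if c != left]))
        if offset + k < 22:
            right = window[offset + k]
            decoys[d][pos + k] = ord(rng.choice([c for c in others if c != right]))
        planted.append({"candidate_start": start, "run_length": k, "decoy_id": f"decoy{d + 1}", "decoy_pos": pos})

    transcripts = isoforms + [
        NucSequence(f"decoy{i + 1}", bytes(d).decode("ascii")) for i, d in enumerate(decoys)
    ]
    txome = Transcriptome(
        transcripts=transcripts,
        target_ids=frozenset(t.id for t in isoforms),
        k=16,
    )
    truth = {"reference_id": reference.id, "cds": cds, "planted": planted, "seed": spec.seed}
    return txome, truth


# ---------------------------------------------------------------------------
# co-expression cell tables

@dataclass(frozen=True)
class CoexprSpec:
    """Study-condition parameters of the co-expression generator.

    Intensities are on the 0-255 gray scale.  Baseline marker intensity is
    a three-component truncated-normal mixture whose components sit inside
    the strong/medium/weak threshold bands, so thresholding reproduces the
    baseline proportions exactly in expectation.  The reporter dose R of a
    penetrant treated cell is Beta-distributed on (0, 1]; marker intensity
    becomes C*(1 - beta*R) + noise and reporter intensity
    dose_scale*R + leakage*C' + noise.
    """

    n_regions_treated: int = 6
    n_regions_untreated: int = 6
    area_range_mm2: tuple[float, float] = (3.0, 8.0)
    density_range: tuple[float, float] = (8.0, 15.0)
    baseline_proportions: tuple[float, float, float] = (0.30, 0.60, 0.10)
    penetrance: float = 0.80
    beta: float = 0.5
    leakage: float = 0.05
    noise_sd: float = 5.0
    # strong/medium/weak truncated-normal components: (low, high, mean, sd)
    chat_bands: tuple = (
        (100.0, 150.0, 120.0, 12.0),   # strong
        (50.0, 100.0, 75.0, 12.0),     # medium
        (5.0, 50.0, 30.0, 10.0),       # weak
    )
    marker_thresholds: tuple[float, float] = (50.0, 100.0)  # weak<t1<=medium<t2<=strong
    dose_shape: tuple[float, float] = (2.0, 2.0)
    dose_scale: float = 180.0
    reporter_thresholds: tuple[float, float, float] = (15.0, 60.0, 120.0)
    construct: str = "hM4Di_CFP-mirE1"
    marker: str = "ChAT"
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.isclose(sum(self.baseline_proportions), 1.0):
            raise ValueError("baseline proportions must sum to 1")
        if not (0.0 <= self.beta <= 1.0):
            raise ValueError("beta must lie in [0, 1]")
        if self.leakage < 0:
            raise ValueError("leakage must be >= 0")
        if list(self.reporter_thresholds) != sorted(self.reporter_thresholds):
            raise ValueError("reporter thresholds must be strictly increasing")
        t1, t2 = self.marker_thresholds
        if not t1 < t2:
            raise ValueError("marker thresholds must be strictly increasing")

    def with_expected_cells(self, n: int) -> "CoexprSpec":
        """Same conditions, region areas rescaled so the expected total
        cell count is about ``n`` (density stays in its stated range)."""
        n_reg = self.n_regions_treated + self.n_regions_untreated
        mean_density = sum(self.density_range) / 2
        area = n / (n_reg * mean_density)
        return replace(self, area_range_mm2=(0.8 * area, 1.2 * area))


def _draw_baseline_intensity(rng: np.random.Generator, spec: CoexprSpec, n: int) -> tuple[np.ndarray, np.ndarray]:
    """(category index 0=strong,1=medium,2=weak; intensity) for n cells."""
    cat = rng.choice(3, size=n, p=list(spec.baseline_proportions))
    c = np.empty(n)
    for i, (lo, hi, mu, sd) in enumerate(spec.chat_bands):
        idx = cat == i
        if idx.any():
            a, b = (lo - mu) / sd, (hi - mu) / sd
            c[idx] = stats.truncnorm.rvs(a, b, loc=mu, scale=sd, size=idx.sum(), random_state=rng)
    return cat, c


def _marker_level(spec: CoexprSpec, c: np.ndarray) -> np.ndarray:
    t1, t2 = spec.marker_thresholds
    return np.where(c >= t2, "strong", np.where(c >= t1, "medium", "weak"))


def _reporter_level(spec: CoexprSpec, rep: np.ndarray) -> np.ndarray:
    t_det, t_med, t_strong = spec.reporter_thresholds
    return np.where(
        rep >= t_strong, "RS",
        np.where(rep >= t_med, "RM", np.where(rep >= t_det, "RW", "RN")),
    )


def simulate_cell_table(spec: CoexprSpec) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate (cells, regions, truth) for one construct.

    Per region the cell count is Poisson(density * area) with density
    uniform in ``density_range``.  The truth record carries the planted
    ``beta`` and ``leakage``, the per-cell reporter dose (0 for
    non-penetrant and untreated cells) and the latent baseline category.
    """
    rng = np.random.default_rng(spec.seed)
    regions = []
    for i in range(spec.n_regions_treated + spec.n_regions_untreated):
        treated = i < spec.n_regions_treated
        regions.append(
            {
                "region_id": f"R{i + 1:02d}",
                "section_id": f"S{i // 2 + 1:02d}",
                "compartment": "caudate" if i % 2 == 0 else "putamen",
                "treated": treated,
                "construct": spec.construct if treated else "",
                "area_mm2": float(rng.uniform(*spec.area_range_mm2)),
            }
        )
    regions_df = pd.DataFrame(regions)

    cells = []
    doses = []
    baseline_cats = []
    cid = 0
    for reg in regions:
        density = rng.uniform(*spec.density_range)
        n = int(rng.poisson(density * reg["area_mm2"]))
        cat, c0 = _draw_baseline_intensity(rng, spec, n)
        baseline_cats.append(cat)
        if reg["treated"]:
            penetrant = rng.random(n) < spec.penetrance
            dose = np.where(penetrant, rng.beta(*spec.dose_shape, size=n), 0.0)
            c = np.clip(c0 * (1.0 - spec.beta * dose) + rng.normal(0, spec.noise_sd, n), 0, 255)
            rep = np.clip(
                spec.dose_scale * dose + spec.leakage * c + rng.normal(0, spec.noise_sd, n),
                0, 255,
            )
            rep_level = _reporter_level(spec, rep)
        else:
            dose = np.zeros(n)
            c = np.clip(c0 + rng.normal(0, spec.noise_sd, n), 0, 255)
            rep = np.clip(spec.leakage * c + rng.normal(0, spec.noise_sd, n), 0, 255)
            rep_level = np.full(n, "RU")
        doses.append(dose)
        cells.append(
            pd.DataFrame(
                {
                    "cell_id": [f"C{cid + j:06d}" for j in range(n)],
                    "section_id": reg["section_id"],
                    "region_id": reg["region_id"],
                    "compartment": reg["compartment"],
                    "treated": reg["treated"],
                    "marker": spec.marker,
                    "marker_level": _marker_level(spec, c),
                    "reporter_level": rep_level,
                    "chat_intensity": c,
                    "reporter_intensity": rep,
                }
            )
        )
        cid += n
    cells_df = pd.concat(cells, ignore_index=True) if cells else pd.DataFrame(
        columns=[
            "cell_id", "section_id", "region_id", "compartment", "treated",
            "marker", "marker_level", "reporter_level",
            "chat_intensity", "reporter_intensity",
        ]
    )
    truth = {
        "beta": spec.beta,
        "leakage": spec.leakage,
        "penetrance": spec.penetrance,
        "dose": np.concatenate(doses) if doses else np.empty(0),
        "baseline_category": np.concatenate(baseline_cats) if baseline_cats else np.empty(0, int),
        "seed": spec.seed,
    }
    return cells_df, regions_df, truth


# ---------------------------------------------------------------------------
# image rendering

def render_images(
    cells: pd.DataFrame,
    spec: CoexprSpec | None = None,
    seed: int = 0,
    shape: tuple[int, int] = (512, 512),
    chat_background: float = 100.0,
    reporter_background: float = 10.0,
    min_separation: int = 30,
    max_cells: int | None = None,
) -> tuple[ChannelImage, ChannelImage, np.ndarray, pd.DataFrame]:
    """Render cells as filled ellipses over Poisson-noise background.

    Cells (up to ``max_cells``) are placed by rejection sampling with a
    centre-to-centre separation of ``min_separation`` px (well-separated
    by default); semi-axes are 4-8 px (8-16 px diameters).  Cell pixels
    are Poisson with mean background + the cell's channel intensity, so
    :func:`shmirkit.imaging.measure_cells` with the true background
    recovers the planted amplitude up to shot noise.  Returns the two
    channel images, the ground-truth label mask, and the placed-cell
    table (with row/col centres); placements that would overlap are
    skipped and noted in the table.
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    chat = rng.poisson(chat_background, size=shape).astype(float)
    rep = rng.poisson(reporter_background, size=shape).astype(float)
    labels = np.zeros(shape, dtype=np.int32)

    subset = cells if max_cells is None else cells.head(max_cells)
    placed = []
    centres: list[tuple[float, float]] = []
    for i, (_, cell) in enumerate(subset.iterrows(), start=1):
        ok = False
        for _try in range(200):
            r0 = rng.uniform(16, h - 16)
            c0 = rng.uniform(16, w - 16)
            if all((r0 - rr) ** 2 + (c0 - cc) ** 2 >= min_separation**2 for rr, cc in centres):
                ok = True
                break
        if not ok:
            placed.append({**cell, "row": np.nan, "col": np.nan, "placed": False})
            continue
        centres.append((r0, c0))
        a, b = rng.uniform(4, 8), rng.uniform(4, 8)
        rot = rng.uniform(0, np.pi)
        rr, cc = draw.ellipse(r0, c0, a, b, shape=shape, rotation=rot)
        labels[rr, cc] = i
        chat[rr, cc] = rng.poisson(chat_background + cell["chat_intensity"], size=rr.size)
        rep[rr, cc] = rng.poisson(reporter_background + cell["reporter_intensity"], size=rr.size)
        placed.append({**cell, "row": r0, "col": c0, "placed": True})

    chat_img = ChannelImage(np.clip(chat, 0, 255).astype(np.uint8), "ChAT")
    rep_img = ChannelImage(np.clip(rep, 0, 255).astype(np.uint8), "reporter")
    return chat_img, rep_img, labels, pd.DataFrame(placed)


# ---------------------------------------------------------------------------
# parameter recovery

@dataclass
class RecoveryResult:
    beta_hat: float
    beta_ci: tuple[float, float]
    lambda_hat: float
    lambda_ci: tuple[float, float]
    n_treated: int
    n_untreated: int


def recover_parameters(cells: pd.DataFrame, dose: np.ndarray) -> RecoveryResult:
    """Estimate the knockdown slope beta and leakage lambda from a
    simulated cell table and its per-cell dose record.

    beta: least squares of treated-cell marker intensity on dose gives
    intercept a ~ E[C] and slope b ~ -E[C]*beta, so beta_hat = -b/a with a
    delta-method CI.  lambda: slope of untreated reporter intensity on
    marker intensity, with the usual normal CI on the slope.
    """
    dose = np.asarray(dose, dtype=float)
    if len(dose) != len(cells):
        raise ValueError("dose record must align with the cell table")
    treated = cells["treated"].to_numpy()
    exposed = treated & (dose > 0)
    if exposed.sum() < 10:
        raise ValueError("insufficient treated (penetrant) cells for recovery")
    x = dose[exposed]
    y = cells.loc[exposed, "chat_intensity"].to_numpy()
    lr = stats.linregress(x, y)
    a, b = lr.intercept, lr.slope
    beta_hat = -b / a
    se = np.sqrt((lr.stderr / a) ** 2 + (b * lr.intercept_stderr / a**2) ** 2)
    beta_ci = (beta_hat - 1.96 * se, beta_hat + 1.96 * se)

    unt = ~treated
    if unt.sum() < 10:
        raise ValueError("insufficient untreated cells for leakage recovery")
    xr = cells.loc[unt, "chat_intensity"].to_numpy()
    yr = cells.loc[unt, "reporter_intensity"].to_numpy()
    lr2 = stats.linregress(xr, yr)
    lam_ci = (lr2.slope - 1.96 * lr2.stderr, lr2.slope + 1.96 * lr2.stderr)
    return RecoveryResult(
        beta_hat=float(beta_hat),
        beta_ci=(float(beta_ci[0]), float(beta_ci[1])),
        lambda_hat=float(lr2.slope),
        lambda_ci=(float(lam_ci[0]), float(lam_ci[1])),
        n_treated=int(exposed.sum()),
        n_untreated=int(unt.sum()),
    )
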