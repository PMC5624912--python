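"""Synthetic expression matrices and Ca2+ recordings with planted truth.

The expression simulator emulates the statistical structure the clustering
pipeline assumes: 96 deeply sequenced neurons in two major classes
(59 gustatory / 37 somatosensory), the gustatory class split into planted
sub-clusters of 33 (T1), 6 (T2) and 18 (T3) cells plus 2 outlier cells that
belong to no sub-cluster, and ~17k expressed genes. Genes are lognormal:
log2 FPKM = per-gene baseline + planted group shifts + per-cell Gaussian
noise, exponentiated to FPKM, with threshold dropout zeroing a fraction of
values below a low-expression cutoff.

Planted gene tiers (disjoint):

* high-expression "housekeeping" genes — high baseline, no group structure;
  together with the major-class markers they populate the mean-FPKM >= 200
  pool that drives first-level clustering.
* major-class markers — shifted up by ``marker_log2_shift`` in all gustatory
  (or all somatosensory) cells.
* sub-cluster markers — carry the gustatory-wide shift (so they survive the
  taste-selective filter, which requires taste-vs-somatosensory enrichment)
  plus an equal extra shift in their own sub-cluster. A configurable
  fraction of T2 markers is additionally expressed at a reduced level in
  somatosensory cells (the Mafb-like shared pattern).
* outlier private genes — taste-selective like sub-cluster markers, but with
  large random per-gene shifts private to one outlier cell, decorrelating
  that cell from every sub-cluster.
* optionally, four named receptor-panel genes (P2rx2, P2rx3, Htr3a, Gabra1)
  at class-dependent levels matching the panel-classification rules.

The trace simulator builds the two-block stimulus protocol (5HT, ATP, KCl,
KCl+GABA, KCl, repeated) at the default 0.67 Hz scan rate with 9-s stimuli
and 81-s gaps, planting transient responses (rise x exponential decay,
truncated to return exactly to baseline within the 40-s scoring window) for
four archetypes: ATP-only, ATP+5HT, 5HT-only, non-responder. The KCl+GABA
peak is scaled by the inverse of the inhibition statistic so the planted
inhibition percentage is exactly recoverable on noiseless traces.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .calcium import (
    BLOCK_SEQUENCE,
    CalciumTrace,
    StimulusEvent,
    StimulusSchedule,
    write_schedule,
    write_traces,
)
from .io import ExpressionMatrix, write_expression_matrix, write_labels

__all__ = [
    "ExpressionSimConfig",
    "SyntheticTruth",
    "GUSTATORY",
    "SOMATOSENSORY",
    "TRACE_ARCHETYPES",
    "simulate_expression",
    "simulate_traces",
    "write_fixture_bundle",
    "verify_bundle",
]

GUSTATORY = "gustatory"
SOMATOSENSORY = "somatosensory"
SUBCLUSTERS = ("T1", "T2", "T3")
OUTLIER = "outlier"

TRACE_ARCHETYPES = ("ATP_only", "ATP_5HT", "5HT_only", "none")
_ARCHETYPE_FLAGS = {
    "ATP_only": (True, False),
    "ATP_5HT": (True, True),
    "5HT_only": (False, True),
    "none": (False, False),
}


@dataclass
class ExpressionSimConfig:
    """Parameters of the planted-cluster expression simulator.

    Defaults reproduce the study conditions: 96 cells split 37 / 33 / 6 /
    18 / 2, ~17k genes, 16-fold (4 log2 units) marker shifts.
    """

    n_genes: int = 17000
    group_sizes: dict = field(
        default_factory=lambda: {
            SOMATOSENSORY: 37, "T1": 33, "T2": 6, "T3": 18, OUTLIER: 2,
        }
    )
    n_markers_per_group: int = 150
    marker_log2_shift: float = 4.0
    baseline_log2_mean_sd: tuple[float, float] = (1.5, 2.0)
    cell_noise_log2_sd: float = 0.4
    dropout_rate_at_low_expression: float = 0.3
    seed: int = 0
    # secondary structure
    n_major_markers: int = 300
    major_marker_baseline_log2_mean_sd: tuple[float, float] = (6.0, 1.0)
    n_high_neutral: int = 250
    high_neutral_log2_mean_sd: tuple[float, float] = (8.5, 0.5)
    subcluster_marker_baseline_log2_mean_sd: tuple[float, float] = (2.0, 1.0)
    n_outlier_private_genes: int = 400
    outlier_private_shift_log2_sd: float = 6.0
    t2_shared_fraction: float = 0.3
    t2_shared_log2_shift: float = 1.0
    dropout_threshold_fpkm: float = 1.0
    include_panel_genes: bool = True

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.group_sizes.values()):
            raise ValueError("group sizes must be positive")
        if not 0 <= self.dropout_rate_at_low_expression <= 1:
            raise ValueError("dropout rate must lie in [0, 1]")
        if not np.isfinite(self.marker_log2_shift):
            raise ValueError("marker shift must be finite")
        needed = (
            4 * self.include_panel_genes
            + self.n_high_neutral
            + 2 * self.n_major_markers
            + 3 * self.n_markers_per_group
            + self.group_sizes.get(OUTLIER, 0) * self.n_outlier_private_genes
        )
        if self.n_genes < needed:
            raise ValueError(
                f"n_genes={self.n_genes} too small for the planted structure "
                f"({needed} structured genes)"
            )

    @property
    def n_cells(self) -> int:
        return sum(self.group_sizes.values())

    def to_dict(self) -> dict:
        d = asdict(self)
        d["baseline_log2_mean_sd"] = list(d["baseline_log2_mean_sd"])
        return d


@dataclass
class SyntheticTruth:
    """Planted ground truth for recovery tests."""

    cell_labels: dict[str, str] = field(default_factory=dict)
    marker_genes: dict[str, set[str]] = field(default_factory=dict)
    trace_truth: dict[str, dict] = field(default_factory=dict)

    def major_labels(self) -> dict[str, str]:
        """Collapse sub-cluster labels to the gustatory/somatosensory split."""
        return {
            c: (SOMATOSENSORY if l == SOMATOSENSORY else GUSTATORY)
            for c, l in self.cell_labels.items()
        }

    def subcluster_labels(self) -> dict[str, str]:
        """Labels of gustatory sub-cluster members only (outliers excluded)."""
        return {c: l for c, l in self.cell_labels.items() if l in SUBCLUSTERS}

    def to_dict(self) -> dict:
        return {
            "cell_labels": dict(self.cell_labels),
            "marker_genes": {k: sorted(v) for k, v in self.marker_genes.items()},
            "trace_truth": self.trace_truth,
        }


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

_PANEL_LEVELS = {
    # gene: log2 FPKM by class (gustatory sub-clusters, outlier, somatosensory)
    "P2rx2": {"T1": 7.0, "T2": -3.0, "T3": 7.0, OUTLIER: 7.0, SOMATOSENSORY: -3.0},
    "P2rx3": {"T1": 7.0, "T2": 7.0, "T3": 7.0, OUTLIER: 7.0, SOMATOSENSORY: -3.0},
    "Htr3a": {"T1": 1.0, "T2": 1.0, "T3": 9.0, OUTLIER: 1.0, SOMATOSENSORY: 1.0},
    "Gabra1": {"T1": 6.0, "T2": 6.0, "T3": 6.0, OUTLIER: 6.0, SOMATOSENSORY: 5.0},
}


def simulate_expression(
    config: ExpressionSimConfig | None = None,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Generate a planted-structure FPKM matrix; reproducible from the seed."""
    cfg = config or ExpressionSimConfig()
    rng = np.random.default_rng(cfg.seed)

    # cells, in a seeded random order so nothing downstream can key on layout
    labels: list[str] = []
    for group, size in cfg.group_sizes.items():
        labels.extend([group] * size)
    order = rng.permutation(len(labels))
    labels = [labels[i] for i in order]
    n_cells = len(labels)
    width = len(str(n_cells))
    cell_ids = [f"cell_{i + 1:0{width}d}" for i in range(n_cells)]
    cell_labels = dict(zip(cell_ids, labels))
    lab = np.array(labels)
    gustatory = np.isin(lab, SUBCLUSTERS + (OUTLIER,))

    # gene ids and tier bookkeeping
    n_panel = 4 if cfg.include_panel_genes else 0
    gwidth = len(str(cfg.n_genes))
    gene_ids = [f"G{i + 1:0{gwidth}d}" for i in range(cfg.n_genes - n_panel)]
    if cfg.include_panel_genes:
        gene_ids = list(_PANEL_LEVELS) + gene_ids

    log2 = np.empty((cfg.n_genes, n_cells))
    truth = SyntheticTruth(cell_labels=cell_labels)
    shift = cfg.marker_log2_shift
    cursor = n_panel

    def take(n: int) -> slice:
        nonlocal cursor
        s = slice(cursor, cursor + n)
        cursor += n
        return s

    # panel genes: fixed class-dependent levels
    for gi, (gene, levels) in enumerate(_PANEL_LEVELS.items() if cfg.include_panel_genes else []):
        log2[gi] = [levels[l] for l in labels]

    # high-expression neutral genes
    s_neutral = take(cfg.n_high_neutral)
    mu, sd = cfg.high_neutral_log2_mean_sd
    log2[s_neutral] = rng.normal(mu, sd, cfg.n_high_neutral)[:, None]

    # major-class markers
    mu, sd = cfg.major_marker_baseline_log2_mean_sd
    s_gust = take(cfg.n_major_markers)
    base = rng.normal(mu, sd, cfg.n_major_markers)[:, None]
    log2[s_gust] = base + shift * gustatory[None, :]
    truth.marker_genes[GUSTATORY] = set(gene_ids[s_gust])

    s_som = take(cfg.n_major_markers)
    base = rng.normal(mu, sd, cfg.n_major_markers)[:, None]
    log2[s_som] = base + shift * (~gustatory)[None, :]
    truth.marker_genes[SOMATOSENSORY] = set(gene_ids[s_som])

    # sub-cluster markers: gustatory-wide shift + equal extra own-cluster shift
    mu, sd = cfg.subcluster_marker_baseline_log2_mean_sd
    for sub in SUBCLUSTERS:
        s_sub = take(cfg.n_markers_per_group)
        base = rng.normal(mu, sd, cfg.n_markers_per_group)[:, None]
        block = base + shift * gustatory[None, :] + shift * (lab == sub)[None, :]
        if sub == "T2" and cfg.t2_shared_fraction > 0:
            n_shared = int(round(cfg.t2_shared_fraction * cfg.n_markers_per_group))
            block[:n_shared] += cfg.t2_shared_log2_shift * (~gustatory)[None, :]
        log2[s_sub] = block
        truth.marker_genes[sub] = set(gene_ids[s_sub])

    # outlier private genes: taste-selective plus large private shifts
    outlier_cells = np.flatnonzero(lab == OUTLIER)
    truth.marker_genes[OUTLIER] = set()
    for oc in outlier_cells:
        s_out = take(cfg.n_outlier_private_genes)
        base = rng.normal(mu, sd, cfg.n_outlier_private_genes)[:, None]
        block = base + shift * gustatory[None, :]
        block[:, oc] += rng.normal(
            0.0, cfg.outlier_private_shift_log2_sd, cfg.n_outlier_private_genes
        )
        log2[s_out] = block
        truth.marker_genes[OUTLIER] |= set(gene_ids[s_out])

    # unstructured baseline genes
    n_rest = cfg.n_genes - cursor
    mu, sd = cfg.baseline_log2_mean_sd
    log2[cursor:] = rng.normal(mu, sd, n_rest)[:, None]

    # per-cell lognormal noise, exponentiation, threshold dropout
    log2 += rng.normal(0.0, cfg.cell_noise_log2_sd, log2.shape)
    fpkm = np.power(2.0, log2)
    low = fpkm < cfg.dropout_threshold_fpkm
    drop = low & (rng.random(fpkm.shape) < cfg.dropout_rate_at_low_expression)
    fpkm[drop] = 0.0

    mat = ExpressionMatrix(fpkm, gene_ids, cell_ids)
    return mat, truth


# ---------------------------------------------------------------------------
# traces
# ---------------------------------------------------------------------------

def _response_kernel(n_frames: int = 24, rise: float = 2.0, decay: float = 6.0) -> np.ndarray:
    """Unit-peak transient (rise x exponential decay), zero at both ends.

    Truncated so the response returns exactly to baseline within 24 frames
    (36 s at the default rate) — inside the 40-s scoring window and well
    before the next pre-stimulus baseline.
    """
    t = np.arange(n_frames, dtype=float)
    shape = (1.0 - np.exp(-t / rise)) * np.exp(-t / decay)
    shape[-1] = 0.0
    return shape / shape.max()


def default_schedule(
    frame_period_s: float = 1.5,
    first_onset: int = 12,
    duration_s: float = 9.0,
    gap_s: float = 81.0,
) -> StimulusSchedule:
    """Two five-stimulus blocks at the standard timing."""
    events = []
    onset = first_onset
    step = math.ceil(duration_s / frame_period_s) + math.ceil(gap_s / frame_period_s)
    for name in BLOCK_SEQUENCE * 2:
        events.append(StimulusEvent(name, onset, duration_s))
        onset += step
    return StimulusSchedule(events)


def simulate_traces(
    n_cells_per_archetype: int = 30,
    noise_sd_over_f: float = 0.02,
    inhibition_levels: Sequence[float] = (70.0, 40.0, 20.0, 50.0),
    seed: int = 0,
    frame_period_s: float = 1.5,
    baseline_f: float = 100.0,
    atp_dff: float = 0.5,
    ht5_dff: float = 0.5,
    kcl_dff: float = 1.0,
    n_frames: int | None = None,
) -> tuple[list[CalciumTrace], StimulusSchedule, SyntheticTruth]:
    """Planted-archetype recordings under the two-block protocol.

    ``inhibition_levels`` gives the planted GABA inhibition (%) for each of
    the four archetypes (ATP-only, ATP+5HT, 5HT-only, non-responder), each
    <= 100; negative values plant potentiation (KCl+GABA peak above the
    flanking KCl peaks).
    """
    if len(inhibition_levels) != len(TRACE_ARCHETYPES):
        raise ValueError(
            f"need one inhibition level per archetype ({len(TRACE_ARCHETYPES)})"
        )
    if any(v > 100 for v in inhibition_levels):
        raise ValueError("inhibition levels cannot exceed 100%")

    schedule = default_schedule(frame_period_s)
    kernel = _response_kernel()
    last = schedule.events[-1]
    window = math.ceil(40.0 / frame_period_s)
    needed = last.onset_frame + max(window, kernel.size) + 10
    if n_frames is None:
        n_frames = needed
    elif n_frames < needed:
        raise ValueError(
            f"n_frames={n_frames} cannot fit the schedule (needs >= {needed})"
        )

    rng = np.random.default_rng(seed)
    traces: list[CalciumTrace] = []
    truth = SyntheticTruth()
    total = n_cells_per_archetype * len(TRACE_ARCHETYPES)
    width = len(str(total))
    i = 0
    for arch, inh in zip(TRACE_ARCHETYPES, inhibition_levels):
        responds_atp, responds_5ht = _ARCHETYPE_FLAGS[arch]
        for _ in range(n_cells_per_archetype):
            i += 1
            cell = f"roi_{i:0{width}d}"
            f = np.full(n_frames, baseline_f)
            for event in schedule:
                if event.name == "ATP":
                    amp = atp_dff if responds_atp else 0.0
                elif event.name == "5HT":
                    amp = ht5_dff if responds_5ht else 0.0
                elif event.name == "KCl":
                    amp = kcl_dff
                else:  # KCl + GABA: invert the inhibition statistic
                    amp = kcl_dff * (1.0 - inh / 100.0)
                if amp != 0.0:
                    sl = slice(event.onset_frame, event.onset_frame + kernel.size)
                    f[sl] += amp * baseline_f * kernel
            if noise_sd_over_f > 0:
                f = f + rng.normal(0.0, noise_sd_over_f * baseline_f, n_frames)
            traces.append(CalciumTrace(cell, f, frame_period_s))
            truth.cell_labels[cell] = arch
            truth.trace_truth[cell] = {
                "responds_ATP": responds_atp,
                "responds_5HT": responds_5ht,
                "inhibition_percent": float(inh),
                "dff_ATP": atp_dff if responds_atp else 0.0,
                "dff_5HT": ht5_dff if responds_5ht else 0.0,
                "dff_KCl": kcl_dff,
            }
    return traces, schedule, truth


# ---------------------------------------------------------------------------
# fixture bundles
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_fixture_bundle(
    outdir: str | Path,
    config: ExpressionSimConfig | None = None,
    trace_kwargs: dict | None = None,
) -> dict:
    """Write matrix, labels, truth, traces and schedule plus a manifest.

    The manifest records the seed, a hash of the full configuration, and a
    sha256 checksum per file, so a bundle can be regenerated byte-identically
    and tampering is detectable via :func:`verify_bundle`.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = config or ExpressionSimConfig()
    trace_kwargs = dict(trace_kwargs or {})
    trace_kwargs.setdefault("seed", cfg.seed)

    mat, truth = simulate_expression(cfg)
    traces, schedule, trace_truth = simulate_traces(**trace_kwargs)
    truth.trace_truth = trace_truth.trace_truth
    for cell, arch in trace_truth.cell_labels.items():
        truth.cell_labels.setdefault(cell, arch)

    files = {
        "matrix.tsv": lambda p: write_expression_matrix(mat, p),
        "labels.csv": lambda p: write_labels(
            {c: truth.cell_labels[c] for c in mat.cell_ids}, p
        ),
        "truth.json": lambda p: p.write_text(
            json.dumps(truth.to_dict(), indent=1, sort_keys=True) + "\n"
        ),
        "traces.csv": lambda p: write_traces(traces, p),
        "schedule.csv": lambda p: write_schedule(schedule, p),
    }
    for name, writer in files.items():
        writer(outdir / name)

    written = sorted(
        ["matrix.tsv", "labels.csv", "truth.json", "traces.csv", "traces.json",
         "schedule.csv"]
    )
    config_blob = json.dumps(
        {"expression": cfg.to_dict(), "traces": trace_kwargs}, sort_keys=True
    )
    manifest = {
        "seed": cfg.seed,
        "config": json.loads(config_blob),
        "config_sha256": hashlib.sha256(config_blob.encode()).hexdigest(),
        "files": {name: _sha256(outdir / name) for name in written},
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n"
    )
    return manifest


def verify_bundle(outdir: str | Path) -> bool:
    """True iff every file listed in the manifest matches its checksum."""
    outdir = Path(outdir)
    manifest = json.loads((outdir / "manifest.json").read_text())
    for name, digest in manifest["files"].items():
        p = outdir / name
        if not p.exists() or _sha256(p) != digest:
            return False
    return True
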