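"""Synthetic data with planted ground truth for the ceRNA pipeline.

Three generators emulate the pipeline's real inputs:

* :func:`simulate_expression` — paired tumor/normal log2-scale expression with
  a planted fraction of differential transcripts and planted co-expressed
  lncRNA-mRNA pairs;
* :func:`simulate_interactions` — two bipartite miRNA-target tables in which
  the planted pairs share an enriched set of common miRNAs;
* :func:`simulate_probe_hits` — a BLAST-tabular-style probe-hit fixture
  exercising every branch of the probe-filtering criteria, with the intended
  outcome logged per probe.

The expression model is log-normal on the intensity scale: log2 values are
``baseline + condition_shift + pair_intercept + noise`` with
``baseline ~ N(6, 1)``.  The per-patient intercept (SD = 0.5 x noise_sd,
shared by the tumor and normal sample of a patient) is what a paired
statistic gains over an unpaired one.  Planted co-expression is achieved by
sharing the patient intercept and condition direction between pair members
and correlating their residual noise by the exact amount needed to hit the
target population Pearson correlation on the pooled samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import (
    CODING,
    LNCRNA,
    MRNA,
    NORMAL,
    TUMOR,
    ExpressionMatrix,
    InteractionTable,
)

BASELINE_MEAN = 6.0
BASELINE_SD = 1.0
PAIR_SD_FACTOR = 0.5  # pair-intercept SD as a fraction of noise_sd


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study.

    Defaults mirror the study conditions the pipeline targets: 20 patient
    pairs (40 arrays), log2-scale noise around half a unit, a modest fraction
    of differential transcripts, and planted ceRNA pairs whose shared-miRNA
    count clearly exceeds the uniform background.
    """

    n_lnc: int = 60
    n_mrna: int = 240
    n_mirna: int = 150
    n_pairs_samples: int = 20
    frac_de: float = 0.25
    de_effect: float = 1.5
    noise_sd: float = 0.5
    n_planted_cerna: int = 12
    shared_mirna_boost: int = 6
    background_degree: float = 5.0
    coexpr_r: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_lnc", "n_mrna", "n_mirna", "n_pairs_samples"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.frac_de <= 1.0:
            raise ValueError(f"frac_de must be in [0, 1], got {self.frac_de}")
        if not 0.0 <= self.coexpr_r <= 1.0:
            raise ValueError(f"coexpr_r must be in [0, 1], got {self.coexpr_r}")
        if self.n_planted_cerna < 0:
            raise ValueError("n_planted_cerna must be non-negative")
        if self.n_planted_cerna > self.n_lnc * self.n_mrna:
            raise ValueError("n_planted_cerna exceeds n_lnc * n_mrna")
        if self.shared_mirna_boost < 0:
            raise ValueError("shared_mirna_boost must be non-negative")
        if self.noise_sd < 0 or self.de_effect < 0 or self.background_degree < 0:
            raise ValueError("noise_sd, de_effect, background_degree must be >= 0")


@dataclass
class GroundTruth:
    """What the generator planted, for downstream recovery checks."""

    de_lnc_ids: set[str]
    de_mrna_ids: set[str]
    planted_pairs: set[tuple[str, str]]
    de_direction: dict[str, int] = field(default_factory=dict)


def _transcript_ids(config: SimulationConfig) -> tuple[list[str], list[str]]:
    lnc = [f"LNC{i:04d}" for i in range(config.n_lnc)]
    mrna = [f"GENE{i:04d}" for i in range(config.n_mrna)]
    return lnc, mrna


def de_allocation(config: SimulationConfig) -> tuple[int, int]:
    """Number of DE-candidate lncRNAs and mRNAs implied by frac_de (stratified)."""
    n_rows = config.n_lnc + config.n_mrna
    n_de = round(config.frac_de * n_rows)
    n_de_lnc = min(round(n_de * config.n_lnc / n_rows), config.n_lnc)
    n_de_mrna = min(n_de - n_de_lnc, config.n_mrna)
    return n_de - n_de_mrna, n_de_mrna


def max_plantable(config: SimulationConfig) -> int:
    """Largest n_planted_cerna the DE allocation can support (pairs are a matching)."""
    n_de_lnc, n_de_mrna = de_allocation(config)
    return min(n_de_lnc, n_de_mrna)


def simulate_expression(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Generate a paired tumor/normal log2 expression matrix with planted truth.

    Exactly ``round(frac_de * n_rows)`` rows carry a mean tumor-normal shift
    of ``+/- de_effect`` (direction split evenly); ``n_planted_cerna``
    lncRNA-mRNA pairs drawn from the shifted rows additionally share latent
    structure so their pooled-sample population correlation equals
    ``coexpr_r`` (or the closest achievable value, see module docstring).
    """
    if config.n_pairs_samples < 2:
        raise ValueError("need at least 2 sample pairs")
    rng = np.random.default_rng(config.seed)
    lnc_ids, mrna_ids = _transcript_ids(config)
    all_ids = lnc_ids + mrna_ids
    n_rows = len(all_ids)
    k = config.n_pairs_samples

    # DE-candidate rows, stratified by class so planted pairs stay feasible
    n_de_lnc, n_de_mrna = de_allocation(config)
    de_lnc = sorted(map(str, rng.choice(lnc_ids, size=n_de_lnc, replace=False)))
    de_mrna = sorted(map(str, rng.choice(mrna_ids, size=n_de_mrna, replace=False)))
    de_all = de_lnc + de_mrna

    if config.n_planted_cerna > min(len(de_lnc), len(de_mrna)):
        raise ValueError(
            "not enough differential lncRNAs/mRNAs to plant "
            f"{config.n_planted_cerna} disjoint ceRNA pairs; raise frac_de"
        )

    # direction of shift, split 50/50 up/down
    directions = np.ones(len(de_all), dtype=int)
    directions[: len(de_all) // 2] = -1
    rng.shuffle(directions)
    direction = dict(zip(de_all, directions))

    # planted pairs: a matching of distinct DE lncRNAs and DE mRNAs,
    # members forced to the same shift direction
    pl_lnc = list(map(str, rng.choice(de_lnc, size=config.n_planted_cerna, replace=False)))
    pl_mrna = list(map(str, rng.choice(de_mrna, size=config.n_planted_cerna, replace=False)))
    planted = set(zip(pl_lnc, pl_mrna))
    for l_id, g_id in planted:
        direction[g_id] = direction[l_id]

    pair_ids = [f"P{i:02d}" for i in range(k)]
    samples = [f"T{i:02d}" for i in range(k)] + [f"N{i:02d}" for i in range(k)]
    design = pd.DataFrame(
        {
            "condition": [TUMOR] * k + [NORMAL] * k,
            "pair": pair_ids + pair_ids,
        },
        index=pd.Index(samples, name="sample"),
    )

    idx = {t: i for i, t in enumerate(all_ids)}
    baseline = rng.normal(BASELINE_MEAN, BASELINE_SD, size=n_rows)
    pair_sd = PAIR_SD_FACTOR * config.noise_sd
    alpha = rng.normal(0.0, pair_sd, size=(n_rows, k))  # per-transcript, per-patient
    eps = rng.normal(0.0, config.noise_sd, size=(n_rows, 2 * k))

    # correlate planted pairs: share patient intercept, correlate residuals
    if config.noise_sd > 0:
        var_total = (
            config.de_effect**2 / 4.0 + pair_sd**2 + config.noise_sd**2
        )
        shared = config.de_effect**2 / 4.0 + pair_sd**2
        rho_resid = (config.coexpr_r * var_total - shared) / config.noise_sd**2
        rho_resid = float(np.clip(rho_resid, -1.0, 1.0))
    else:
        rho_resid = 0.0
    for l_id, g_id in planted:
        li, gi = idx[l_id], idx[g_id]
        alpha[gi] = alpha[li]
        fresh = rng.normal(0.0, config.noise_sd, size=2 * k)
        eps[gi] = rho_resid * eps[li] + np.sqrt(max(0.0, 1 - rho_resid**2)) * fresh

    shift = np.zeros(n_rows)
    if config.de_effect > 0:
        for t in de_all:
            shift[idx[t]] = direction[t] * config.de_effect

    tumor_flag = np.array([1.0] * k + [0.0] * k)
    alpha_full = np.concatenate([alpha, alpha], axis=1)  # tumor then normal columns
    values = (
        baseline[:, None]
        + shift[:, None] * tumor_flag[None, :]
        + alpha_full
        + eps
    )
    values_df = pd.DataFrame(values, index=all_ids, columns=samples)
    classes = pd.Series(
        [LNCRNA] * config.n_lnc + [MRNA] * config.n_mrna, index=all_ids, name="class"
    )

    if config.de_effect > 0:
        truth = GroundTruth(set(de_lnc), set(de_mrna), planted, direction)
    else:
        truth = GroundTruth(set(), set(), planted, {})
    return ExpressionMatrix(values_df, design, classes), truth


def simulate_interactions(
    config: SimulationConfig, truth: GroundTruth
) -> tuple[InteractionTable, InteractionTable]:
    """Generate lncRNA-miRNA and mRNA-miRNA bipartite interaction tables.

    Each gene-miRNA edge is present independently with probability
    ``background_degree / n_mirna`` (so gene degree has mean
    ``background_degree``); every planted pair additionally receives
    ``shared_mirna_boost`` common miRNAs beyond the background.
    """
    if config.shared_mirna_boost > config.n_mirna:
        raise ValueError("shared_mirna_boost cannot exceed n_mirna")
    rng = np.random.default_rng([1, config.seed])
    lnc_ids, mrna_ids = _transcript_ids(config)
    mirna_ids = np.array([f"MIR{i:04d}" for i in range(config.n_mirna)])
    p_bg = min(1.0, config.background_degree / config.n_mirna)

    def background(genes: list[str]) -> set[tuple[str, str]]:
        mask = rng.random((len(genes), config.n_mirna)) < p_bg
        gi, mi = np.nonzero(mask)
        return {(genes[g], str(mirna_ids[m])) for g, m in zip(gi, mi)}

    lnc_edges = background(lnc_ids)
    mrna_edges = background(mrna_ids)
    for l_id, g_id in sorted(truth.planted_pairs):
        boost = rng.choice(
            mirna_ids, size=config.shared_mirna_boost, replace=False
        )
        for m in boost:
            lnc_edges.add((l_id, str(m)))
            mrna_edges.add((g_id, str(m)))

    def table(edges: set[tuple[str, str]], gene_class: str) -> InteractionTable:
        rows = sorted(edges)
        return InteractionTable(
            pd.DataFrame(rows, columns=["gene_id", "mirna_id"]), gene_class
        )

    return table(lnc_edges, LNCRNA), table(mrna_edges, MRNA)


@dataclass
class ProbeHitFixture:
    """BLAST-style hit rows plus the generator's intended filtering outcome."""

    hits: pd.DataFrame  # probe_id, transcript_id, transcript_class, match_length, identity_pct
    kept_probes: set[str]
    kept_transcripts: set[str]


def simulate_probe_hits(
    config: SimulationConfig, perfect_match_length: int = 60
) -> ProbeHitFixture:
    """Emit a probe-hit table covering every filtering branch, with logged truth.

    The fixture contains, by construction: probes matching exactly one
    transcript; a probe matching both a coding and a lncRNA transcript; a
    probe matching two transcripts of one class; transcripts supported by
    exactly 3 (dropped) and by >= 4 (kept) probes; and hits one nucleotide
    short of the perfect match length, which never survive.
    """
    rng = np.random.default_rng([2, config.seed])
    L = perfect_match_length
    rows: list[tuple[str, str, str, int, float]] = []
    kept_probes: set[str] = set()
    kept_transcripts: set[str] = set()

    def add(probe, transcript, t_class, length=None, identity=100.0):
        rows.append((probe, transcript, t_class, length if length else L, identity))

    # kept coding transcript: 5 clean perfect-match probes
    for i in range(5):
        add(f"PR_C{i}", "TC_KEEP", CODING)
        kept_probes.add(f"PR_C{i}")
    kept_transcripts.add("TC_KEEP")

    # kept lncRNA transcript: exactly 4 clean probes (boundary: > 3)
    for i in range(4):
        add(f"PR_L{i}", "TL_KEEP", LNCRNA)
        kept_probes.add(f"PR_L{i}")
    kept_transcripts.add("TL_KEEP")

    # exactly 3 supporting probes -> transcript dropped (boundary: not > 3)
    for i in range(3):
        add(f"PR_T{i}", "TC_THREE", CODING)

    # probe hitting both classes -> probe removed; TC_KEEP unaffected (5 remain)
    add("PR_XCLASS", "TC_KEEP", CODING)
    add("PR_XCLASS", "TL_AMBIG", LNCRNA)

    # probe hitting two coding transcripts -> removed by within-class criterion
    add("PR_MULTI", "TC_MULTI_A", CODING)
    add("PR_MULTI", "TC_MULTI_B", CODING)

    # transcript that would be kept but one probe is cross-class: 3 survive -> dropped
    for i in range(3):
        add(f"PR_E{i}", "TC_EDGE", CODING)
    add("PR_E3", "TC_EDGE", CODING)
    add("PR_E3", "TL_EDGE", LNCRNA)

    # sub-perfect hits: length L-1 or identity < 100, never kept
    for i in range(4):
        add(f"PR_SHORT{i}", "TC_SHORT", CODING, length=L - 1)
    add("PR_IMPERFECT", "TC_KEEP", CODING, identity=float(rng.uniform(90, 99.9)))

    hits = pd.DataFrame(
        rows,
        columns=[
            "probe_id",
            "transcript_id",
            "transcript_class",
            "match_length",
            "identity_pct",
        ],
    )
    # shuffle rows: downstream filtering must be order-independent
    hits = hits.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(
        drop=True
    )
    return ProbeHitFixture(hits, kept_probes, kept_transcripts)


def write_truth(truth: GroundTruth, path) -> None:
    """Serialize planted ground truth as JSON."""
    import json

    payload = {
        "de_lnc_ids": sorted(truth.de_lnc_ids),
        "de_mrna_ids": sorted(truth.de_mrna_ids),
        "planted_pairs": sorted(list(p) for p in truth.planted_pairs),
        "de_direction": {k: int(v) for k, v in sorted(truth.de_direction.items())},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def read_truth(path) -> GroundTruth:
    import json

    with open(path) as fh:
        payload = json.load(fh)
    return GroundTruth(
        set(payload["de_lnc_ids"]),
        set(payload["de_mrna_ids"]),
        {tuple(p) for p in payload["planted_pairs"]},
        {k: int(v) for k, v in payload["de_direction"].items()},
    )
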