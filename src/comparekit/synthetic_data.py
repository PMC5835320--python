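"""Synthetic inputs with the statistical structure each pipeline stage assumes.

Three generators cover the three data modalities the pipeline consumes:

- :func:`gen_expression_response` — a genes x cell-lines log2 expression
  matrix over a ~58-line panel together with a log10 IC50 response profile,
  with a planted subset of genes correlated (positively and negatively, at a
  target |Pearson r|) with the response;
- :func:`gen_promoters` — background promoter sequences with a motif
  instance planted into a stated fraction of them;
- :func:`gen_dose_response` — replicated 4-parameter-logistic viability
  measurements with multiplicative noise.

All generators are fully reproducible given their seed; the single seed is
expanded into per-component substreams (via ``numpy.random.SeedSequence``)
so individual stages can be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

import numpy as np
import pandas as pd

from .io_formats import PWM, ExpressionMatrix, ResponseVector, ValidationError

#: centre of the simulated log10 IC50 (log10 molar) distribution; the
#: sensitive/resistant partition threshold of the real panel sits on this scale
RESPONSE_MEAN = -5.45
RESPONSE_SD = 0.8

_ALPHABET = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Parameters of the planted-correlation expression/response simulation."""

    n_genes: int = 2000
    n_lines: int = 58
    n_planted_pos: int = 20
    n_planted_neg: int = 20
    rho: float = 0.6
    noise_sd: float = 1.0
    seed: int = 0
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_lines < 3:
            raise ValidationError("need n_genes >= 1 and n_lines >= 3")
        if self.n_planted_pos < 0 or self.n_planted_neg < 0:
            raise ValidationError("planted counts must be non-negative")
        if self.n_planted_pos + self.n_planted_neg > self.n_genes:
            raise ValidationError("more planted genes than genes")
        if not 0.0 < self.rho < 1.0:
            raise ValidationError("rho must lie strictly in (0, 1)")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")


@dataclass
class PlantedTruth:
    """Ground truth of a simulation: which genes/sequences carry signal."""

    planted_pos_ids: list[str] = field(default_factory=list)
    planted_neg_ids: list[str] = field(default_factory=list)
    true_ic50s: np.ndarray | None = None
    planted_motif_id: str | None = None
    #: sequence id -> 0-based offset of the planted motif instance
    planted_positions: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.planted_pos_ids) & set(self.planted_neg_ids):
            raise ValidationError("planted id lists overlap")


def gen_expression_response(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, ResponseVector, PlantedTruth]:
    """Simulate an expression matrix and response profile with planted signal.

    The response is drawn from N(-5.45, 0.8) log10 molar.  Each planted gene
    is ``baseline + a * (response - mean(response)) + noise`` with the
    coefficient ``a`` signed (+ for resistance-associated, - for
    sensitivity-associated) and scaled against the realized sample sd of the
    response so the expected sample |Pearson r| equals ``rho``:

        |r| = |a| sd(resp) / sqrt(a^2 var(resp) + noise_sd^2)
        =>  |a| = rho * noise_sd / (sd(resp) * sqrt(1 - rho^2))

    Non-planted genes are independent baseline noise.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_resp, rng_expr, rng_pick = (
        np.random.default_rng(s) for s in ss.spawn(3)
    )

    resp_values = rng_resp.normal(RESPONSE_MEAN, RESPONSE_SD, config.n_lines)
    resp_centered = resp_values - resp_values.mean()
    sd_resp = resp_values.std(ddof=0)

    width = len(str(config.n_genes))
    gene_ids = [f"G{i + 1:0{width}d}" for i in range(config.n_genes)]
    line_ids = [f"CL{j + 1:02d}" for j in range(config.n_lines)]

    n_planted = config.n_planted_pos + config.n_planted_neg
    planted_idx = rng_pick.choice(config.n_genes, size=n_planted, replace=False)
    pos_idx = planted_idx[: config.n_planted_pos]
    neg_idx = planted_idx[config.n_planted_pos:]

    a = config.rho * config.noise_sd / (sd_resp * np.sqrt(1.0 - config.rho**2))

    values = rng_expr.normal(
        config.baseline_mean, config.baseline_sd,
        (config.n_genes, config.n_lines),
    )
    planted_noise = rng_expr.normal(
        0.0, config.noise_sd, (n_planted, config.n_lines)
    )
    for k, i in enumerate(pos_idx):
        values[i] = config.baseline_mean + a * resp_centered + planted_noise[k]
    for k, i in enumerate(neg_idx, start=config.n_planted_pos):
        values[i] = config.baseline_mean - a * resp_centered + planted_noise[k]

    expr = ExpressionMatrix(gene_ids=gene_ids, cellline_ids=line_ids,
                            values=values)
    resp = ResponseVector(cellline_ids=line_ids, log10_ic50=resp_values)
    truth = PlantedTruth(
        planted_pos_ids=[gene_ids[i] for i in pos_idx],
        planted_neg_ids=[gene_ids[i] for i in neg_idx],
        true_ic50s=resp_values.copy(),
    )
    return expr, resp, truth


def gen_promoters(
    n_seqs: int,
    length: int,
    motif: PWM,
    plant_rate: float,
    seed: int = 0,
    background: np.ndarray | None = None,
) -> tuple[list[tuple[str, str]], PlantedTruth]:
    """Simulate promoter sequences with a motif planted into a fraction of them.

    Backgrounds are i.i.d. draws from ``background`` (default uniform over
    A/C/G/T).  In ``ceil(plant_rate * n_seqs)`` sequences one motif instance,
    sampled column-wise from the PWM, replaces the background at a random
    offset.  Returns ``(records, truth)`` where records are (id, sequence)
    pairs and ``truth.planted_positions`` maps planted ids to offsets.
    """
    if not 0.0 <= plant_rate <= 1.0:
        raise ValidationError("plant_rate must lie in [0, 1]")
    if length <= len(motif):
        raise ValidationError(
            f"sequence length {length} must exceed motif length {len(motif)}"
        )
    if background is None:
        background = np.full(4, 0.25)
    background = np.asarray(background, dtype=float)

    ss = np.random.SeedSequence(seed)
    rng_bg, rng_plant = (np.random.default_rng(s) for s in ss.spawn(2))

    n_planted = ceil(plant_rate * n_seqs)
    planted = set(rng_plant.choice(n_seqs, size=n_planted, replace=False))

    records: list[tuple[str, str]] = []
    positions: dict[str, int] = {}
    L = len(motif)
    for i in range(n_seqs):
        seq_id = f"P{i + 1:04d}"
        bases = rng_bg.choice(4, size=length, p=background)
        if i in planted:
            offset = int(rng_plant.integers(0, length - L + 1))
            instance = np.array(
                [rng_plant.choice(4, p=motif.matrix[:, c]) for c in range(L)]
            )
            bases[offset:offset + L] = instance
            positions[seq_id] = offset
        records.append((seq_id, "".join(_ALPHABET[bases])))

    truth = PlantedTruth(
        planted_motif_id=motif.motif_id if n_planted else None,
        planted_positions=positions,
    )
    return records, truth


def gen_dose_response(
    ic50: float,
    hill: float = 1.0,
    conc_grid: np.ndarray | list[float] | None = None,
    noise_sd: float = 0.1,
    seed: int = 0,
    n_replicates: int = 6,
    cellline: str = "SYN",
) -> pd.DataFrame:
    """Simulate replicated viability measurements from a logistic curve.

    Viability at concentration ``c`` (micromolar) is
    ``1 / (1 + (c / ic50) ** hill)`` times multiplicative noise
    ``(1 + N(0, noise_sd))``, clipped to [0, 1.2] (readout can exceed the
    untreated control slightly).  Six replicates per concentration by
    default.  Returns a tidy table with columns cellline, concentration_uM,
    viability, replicate.
    """
    if ic50 <= 0:
        raise ValidationError("ic50 must be positive")
    if conc_grid is None:
        conc_grid = np.geomspace(0.003, 500.0, 12)  # assay range, micromolar
    conc = np.asarray(conc_grid, dtype=float)
    if np.any(conc <= 0) or np.any(np.diff(conc) <= 0):
        raise ValidationError("conc_grid must be positive and ascending")
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    rows = []
    for c in conc:
        true_v = 1.0 / (1.0 + (c / ic50) ** hill)
        for rep in range(1, n_replicates + 1):
            noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            v = np.clip(true_v * (1.0 + noise), 0.0, 1.2)
            rows.append((cellline, c, v, rep))
    return pd.DataFrame(
        rows, columns=["cellline", "concentration_uM", "viability", "replicate"]
    )
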