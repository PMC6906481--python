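"""Synthetic compound datasets with the statistical structure the renal
excretion pipeline assumes.

Each synthetic compound is built from hidden mechanistic truth: a fraction
unbound in plasma (log-uniform over two decades, as plasma binding spans in
drug-like space), plus a type-specific mechanism — a fraction reabsorbed FR
for reabsorption-type compounds, a secretion clearance CLs for
secretion-type compounds, or neither for intermediate-type compounds whose
clearance is pure filtration.  CLs is sampled as fu,p times a log-normal
intrinsic secretion clearance: only unbound drug is accessible to the
tubular transporters, and this coupling reproduces the strong within-type
correlation of log CLr with fu,p that real clearance data show in every
excretion type (roughly r ≈ 0.7–1.0), not just the filtration-dominated
one.  Observed CLr is the mechanistic forward model
times multiplicative log-normal noise (inter-study variability); compounds
are rejection-resampled until the observed clearance ratio reproduces the
intended type, so stored labels are self-consistent with the banding rule.
The "predicted" fu,p column is the observed value with additional
log-normal error (0.15 decades, placing ~95% of predictions within 2-fold
of observed), emulating an optimistic upstream in-silico fu,p predictor.

The descriptor matrix plants informative features — noisy monotone
transforms of the hidden truth (log10 CLr, log10 fu,p, mechanism
indicators, the lipophilicity latent behind fe) — among independent Gaussian
noise features, so feature selection and regression have a recoverable
signal.  No realistic chemical structures are generated; a small fixture
list of real drug SMILES is provided for integration tests of the real
featurizer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import CompoundRecord
from .featurize import BLOCKS, DescriptorMatrix
from .pk_core import (
    DEFAULT_CONSTANTS,
    CRType,
    MechanismParams,
    PhysiologyConstants,
    classify_cr_type,
    compute_cr,
    forward_clr,
)

__all__ = ["SyntheticConfig", "generate_pk_table", "generate_descriptor_matrix", "fixture_structures"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings.

    Type counts default to 94 reabsorption / 86 intermediate / 180 secretion
    compounds, the composition of the clearance dataset the pipeline is
    designed around.  ``noise_sd_log10`` is the multiplicative observation
    noise on CLr (0.15 decades ≈ 1.4-fold scatter);
    ``fup_pred_sd_log10`` is the extra error on the predicted-fu,p column
    (0.15 decades puts ~95% of predictions within 2-fold of observed).
    """

    n_R: int = 94
    n_IM: int = 86
    n_S: int = 180
    fup_log10_range: tuple = (-2.0, 0.0)  # log-uniform over [0.01, 1]
    fr_range: tuple = (0.4, 0.99)  # uniform, R type
    cls_median: float = 1.5  # mL/min/kg, realized CLs median, S type
    cls_sd_log10: float = 0.4  # spread of the intrinsic secretion clearance
    noise_sd_log10: float = 0.15
    fup_pred_sd_log10: float = 0.15
    fe_slope: float = -1.5  # logistic link on the lipophilicity latent
    fe_intercept: float = -0.3
    p_informative: int = 6
    p_noise: int = 60
    feature_noise_sd: float = 0.8  # on standardized planted signals
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_R, self.n_IM, self.n_S) < 0:
            raise ValueError("type counts must be non-negative")
        if self.noise_sd_log10 < 0 or self.fup_pred_sd_log10 < 0:
            raise ValueError("noise standard deviations must be non-negative")
        lo, hi = self.fr_range
        if not (0 <= lo < hi < 1):
            raise ValueError("fr_range must lie within [0, 1)")


def _expit(z):
    return 1.0 / (1.0 + np.exp(-z))


def generate_pk_table(
    config: SyntheticConfig,
    constants: PhysiologyConstants = DEFAULT_CONSTANTS,
) -> tuple[list[CompoundRecord], pd.DataFrame]:
    """Sample a compound table with self-consistent excretion-type labels.

    Returns ``(records, truth)`` where ``truth`` is a per-compound frame of
    the hidden mechanistic parameters (fup, fr, cls, noiseless CLr, the
    lipophilicity latent, and the intended type).  Records carry observed
    CLr (noisy), fe (logistic link on the latent), fup_observed and
    fup_predicted.  Rejection resampling guarantees that banding the
    observed CR reproduces the intended type; a type needing more than 99%
    rejections is a configuration error.
    """
    rng = np.random.default_rng(config.seed)
    plan = (
        [CRType.R] * config.n_R + [CRType.IM] * config.n_IM + [CRType.S] * config.n_S
    )
    records: list[CompoundRecord] = []
    truth_rows = []
    attempts_by_type = {t: [0, 0] for t in CRType}  # [accepted, tried]
    lo_f, hi_f = config.fup_log10_range
    for i, cr_type in enumerate(plan):
        accepted = None
        for _ in range(10_000):
            attempts_by_type[cr_type][1] += 1
            fup = float(10.0 ** rng.uniform(lo_f, hi_f))
            fr, cls = 0.0, 0.0
            if cr_type is CRType.R:
                fr = float(rng.uniform(*config.fr_range))
            elif cr_type is CRType.S:
                # CLs = fu,p × intrinsic secretion clearance (only unbound
                # drug reaches the transporters); the intrinsic median is set
                # so the realized CLs keeps cls_median at the median fup.
                fup_median = 10.0 ** ((lo_f + hi_f) / 2.0)
                cls_int = float(
                    (config.cls_median / fup_median)
                    * 10.0 ** rng.normal(0.0, config.cls_sd_log10)
                )
                cls = fup * cls_int
            params = MechanismParams(fup=fup, fr=fr, cls=cls)
            clr_true = forward_clr(params, constants)
            clr_obs = clr_true * 10.0 ** rng.normal(0.0, config.noise_sd_log10)
            observed_type = classify_cr_type(
                compute_cr(clr_obs, fup, constants), constants
            )
            if observed_type is cr_type:
                accepted = (params, clr_true, clr_obs)
                attempts_by_type[cr_type][0] += 1
                break
        if accepted is None:
            raise ValueError(
                f"rejection sampling failed for type {cr_type.value}; "
                "config distributions are inconsistent with the banding rule"
            )
        params, clr_true, clr_obs = accepted
        latent = float(rng.normal(0.0, 1.0))
        fe = float(_expit(config.fe_intercept + config.fe_slope * latent))
        fup_pred = float(
            min(1.0, max(1e-6, params.fup * 10.0 ** rng.normal(0.0, config.fup_pred_sd_log10)))
        )
        cid = f"SYN{i:04d}"
        records.append(
            CompoundRecord(
                compound_id=cid,
                smiles=None,
                fe=fe,
                clr=clr_obs,
                fup_observed=params.fup,
                fup_predicted=fup_pred,
                cr_type=cr_type,
            )
        )
        truth_rows.append(
            {
                "compound_id": cid,
                "cr_type": cr_type.value,
                "fup": params.fup,
                "fr": params.fr,
                "cls": params.cls,
                "clr_true": clr_true,
                "clr_observed": clr_obs,
                "lipophilicity_latent": latent,
                "fe": fe,
            }
        )
    for cr_type, (acc, tried) in attempts_by_type.items():
        if tried and acc and acc / tried < 0.01:
            raise ValueError(
                f"rejection rate above 99% for type {cr_type.value}"
            )
    truth = pd.DataFrame(truth_rows).set_index("compound_id")
    return records, truth


def generate_descriptor_matrix(
    records: list[CompoundRecord],
    config: SyntheticConfig,
    truth: pd.DataFrame,
) -> DescriptorMatrix:
    """Plant informative descriptors among Gaussian noise columns.

    Informative columns are standardized monotone transforms of the hidden
    truth (cycling over log10 CLr, log10 fu,p, R/S mechanism indicators, the
    lipophilicity latent and log10 CLs) plus Gaussian noise of
    ``feature_noise_sd``; noise columns are independent standard normals.
    Block labels are assigned round-robin over the fingerprint/descriptor
    blocks for bookkeeping realism; planted values are continuous, so
    downstream code must not assume binary fingerprints here.
    """
    rng = np.random.default_rng(config.seed + 1)
    ids = [r.compound_id for r in records]
    t = truth.loc[ids]

    def z(v):
        v = np.asarray(v, dtype=float)
        sd = v.std()
        return (v - v.mean()) / (sd if sd > 0 else 1.0)

    signals = [
        ("log_clr", z(np.log10(t["clr_true"]))),
        ("log_fup", z(np.log10(t["fup"]))),
        ("is_reabsorbed", z((t["cr_type"] == "R").astype(float))),
        ("is_secreted", z((t["cr_type"] == "S").astype(float))),
        ("lipophilicity", z(t["lipophilicity_latent"])),
        ("log_cls", z(np.log10(t["cls"] + 1e-3))),
    ]
    columns: dict[str, np.ndarray] = {}
    block_of: dict[str, str] = {}
    cycle_blocks = [b for b in BLOCKS if b != "fup"]
    for j in range(config.p_informative):
        name, base = signals[j % len(signals)]
        col = f"inf{j:03d}_{name}"
        columns[col] = base + rng.normal(0.0, config.feature_noise_sd, len(ids))
        block_of[col] = cycle_blocks[j % len(cycle_blocks)]
    for j in range(config.p_noise):
        col = f"noise{j:03d}"
        columns[col] = rng.normal(0.0, 1.0, len(ids))
        block_of[col] = cycle_blocks[j % len(cycle_blocks)]
    values = pd.DataFrame(columns, index=pd.Index(ids, name="compound_id"))
    return DescriptorMatrix(
        values=values,
        block_of=block_of,
        provenance={"backend": "synthetic", "seed": config.seed},
    )


#: Drug-like fixtures spanning acids, bases, neutrals and a zwitterion,
#: for integration tests of the real RDKit featurizer.
_FIXTURES = (
    ("aspirin", "CC(=O)Oc1ccccc1C(=O)O"),
    ("ibuprofen", "CC(C)Cc1ccc(cc1)C(C)C(=O)O"),
    ("furosemide", "NS(=O)(=O)c1cc(C(=O)O)c(NCc2ccco2)cc1Cl"),
    ("atenolol", "CC(C)NCC(O)COc1ccc(CC(N)=O)cc1"),
    ("metformin", "CN(C)C(=N)NC(=N)N"),
    ("propranolol", "CC(C)NCC(O)COc1cccc2ccccc12"),
    ("caffeine", "Cn1cnc2c1c(=O)n(C)c(=O)n2C"),
    ("paracetamol", "CC(=O)Nc1ccc(O)cc1"),
    ("diazepam", "CN1c2ccc(Cl)cc2C(=NCC1=O)c1ccccc1"),
    ("digoxin_aglycone", "CC12CCC(O)CC1CCC1C2CCC2(C)C(C3=CC(=O)OC3)CCC12O"),
    ("ciprofloxacin", "OC(=O)c1cn(C2CC2)c2cc(N3CCNCC3)c(F)cc2c1=O"),
    ("gabapentin", "NCC1(CC(=O)O)CCCCC1"),
)


def fixture_structures() -> list[tuple[str, str]]:
    """A stable, parseable list of (name, SMILES) drug structures."""
    return [tuple(pair) for pair in _FIXTURES]
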