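"""Packaged placental-permeability dataset and a synthetic QSAR generator.

The packaged fixture is the 88-compound clearance-index (CI) table from the
ex vivo placental-perfusion literature: observed CI for every compound,
model-calculated CI where available, the train/test split, and mefloquine
(CI = 1.57, far above the rest) flagged as the excluded outlier.  CI is the
clearance of a compound relative to antipyrine.

Because the accompanying DRAGON descriptor matrix is commercial and not
redistributable, :func:`generate_synthetic_qsar` builds a descriptor table
with the same pathologies a raw descriptor pool exhibits — a low-rank latent
structure driving the response, irrelevant noise columns, near-duplicate
correlated blocks, and constant columns — with full ground truth, so every
pipeline stage is testable end to end.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "PlacentaRecord",
    "SyntheticTruth",
    "load_placenta_dataset",
    "placenta_frame",
    "train_test_arrays",
    "generate_synthetic_qsar",
    "REPORTED_STATS",
    "REPORTED_SELECTION_TRACE",
]

_FIXTURE_NAME = "placenta_ci.csv"
_FIXTURE_SHA256 = "6b2f7a5a29dd8b81cb5409cb1c8e26ed50f4a3c3874f78b11d034d3aa22ea64e"

#: Published reference statistics of the CI model, used by the fixture
#: self-check (``qsar validate-fixture``).
REPORTED_STATS = {
    "r2_train": 0.9064,
    "rmse_train": 0.09,
    "f_train": 78.86,
    "n_train": 65,
    "A": 7,
    "m": 48,
    "r_p2_22": 0.4201,
    "rmsp_22": 0.23,
    "r_p2_19": 0.7656,
    "rmsp_19": 0.14,
    "k": 0.9282,
    "k_prime": 1.0084,
    "h_star": 2.22,
    "outlier_nos": (53, 68, 75),
}

#: Published VIP-selection trace of the CI model (m, A, r2, RMSE, q2, RMSV),
#: one row per iteration from the 620-descriptor pool down to 34.
REPORTED_SELECTION_TRACE = [
    (620, 8, 0.9801, 0.04, 0.3715, 0.25),
    (396, 7, 0.9716, 0.05, 0.5569, 0.20),
    (286, 8, 0.9745, 0.05, 0.6532, 0.18),
    (235, 8, 0.9751, 0.05, 0.6773, 0.17),
    (195, 7, 0.9573, 0.06, 0.6984, 0.16),
    (163, 7, 0.9651, 0.06, 0.7445, 0.15),
    (137, 7, 0.9518, 0.07, 0.7153, 0.16),
    (115, 7, 0.9368, 0.07, 0.6941, 0.17),
    (100, 7, 0.9264, 0.08, 0.6831, 0.17),
    (85, 7, 0.9302, 0.08, 0.7125, 0.16),
    (79, 7, 0.9341, 0.08, 0.7560, 0.15),
    (73, 7, 0.9258, 0.08, 0.7330, 0.15),
    (67, 7, 0.9169, 0.09, 0.7022, 0.16),
    (62, 7, 0.9138, 0.09, 0.7271, 0.16),
    (58, 7, 0.9110, 0.09, 0.7208, 0.16),
    (55, 7, 0.9115, 0.09, 0.7303, 0.15),
    (48, 7, 0.9064, 0.09, 0.7323, 0.15),
    (42, 7, 0.8525, 0.11, 0.6655, 0.17),
    (39, 5, 0.8115, 0.13, 0.6350, 0.18),
    (34, 5, 0.7845, 0.14, 0.6138, 0.19),
]


@dataclass
class PlacentaRecord:
    no: int
    name: str
    name_printed: str
    ci_obs: float
    ci_calc: float | None
    set: str  # "train" or "test"
    excluded: bool


def _fixture_bytes() -> bytes:
    return resources.files("plsvip.datasets").joinpath(_FIXTURE_NAME).read_bytes()


def load_placenta_dataset() -> list[PlacentaRecord]:
    """Load the 88-record CI table; the file checksum is validated first."""
    raw = _fixture_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _FIXTURE_SHA256:
        raise RuntimeError(
            f"packaged dataset corrupted (sha256 {digest[:12]}..., expected {_FIXTURE_SHA256[:12]}...)"
        )
    from io import BytesIO

    df = pd.read_csv(BytesIO(raw))
    records = [
        PlacentaRecord(
            no=int(r.no),
            name=str(r.name),
            name_printed=str(r.name_printed),
            ci_obs=float(r.ci_obs),
            ci_calc=None if pd.isna(r.ci_calc) else float(r.ci_calc),
            set=str(r.set),
            excluded=bool(r.excluded),
        )
        for r in df.itertuples()
    ]
    if len(records) != 88:
        raise RuntimeError("expected 88 records in the packaged dataset")
    return records


def placenta_frame() -> pd.DataFrame:
    """The packaged table as a DataFrame (one row per compound)."""
    return pd.DataFrame([vars(r) for r in load_placenta_dataset()])


def train_test_arrays() -> dict[str, np.ndarray]:
    """Observed/calculated CI arrays for the 65 training and 22 test compounds.

    Keys: ``obs_train``, ``calc_train``, ``obs_test``, ``calc_test``,
    ``no_train``, ``no_test``.  The excluded compound (mefloquine) appears in
    neither.
    """
    df = placenta_frame()
    tr = df[(df["set"] == "train") & ~df["excluded"]]
    te = df[df["set"] == "test"]
    return {
        "obs_train": tr["ci_obs"].to_numpy(float),
        "calc_train": tr["ci_calc"].to_numpy(float),
        "no_train": tr["no"].to_numpy(int),
        "obs_test": te["ci_obs"].to_numpy(float),
        "calc_test": te["ci_calc"].to_numpy(float),
        "no_test": te["no"].to_numpy(int),
    }


@dataclass
class SyntheticTruth:
    """Ground truth of a generated descriptor table."""

    informative_names: list[str]
    noise_names: list[str]
    correlated_block_map: dict[str, list[str]]
    constant_names: list[str]
    latent_rank: int
    noise_sd: float
    seed: int

    @property
    def block_member_names(self) -> list[str]:
        return [n for members in self.correlated_block_map.values() for n in members]


def generate_synthetic_qsar(
    n: int = 87,
    n_informative: int = 10,
    n_noise: int = 180,
    n_corr_blocks: int = 3,
    block_size: int = 4,
    n_constant: int = 10,
    latent_rank: int = 3,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, SyntheticTruth]:
    """Generate a descriptor table, response and ground truth.

    ``latent_rank`` standard-normal latent factors drive both the response
    (y = Z·β + N(0, noise_sd), β unit norm) and the informative descriptors
    (exact random linear combinations of the latents, so the noiseless limit
    is exactly recoverable).  Noise descriptors are iid N(0,1); each
    correlated block is one N(0,1) base column plus jitter of SD 0.1
    (pairwise |r| ≈ 0.995); constant columns take a single drawn value.
    Columns are shuffled into a single table.  Fully deterministic per seed.
    """
    if latent_rank < 1 or n < latent_rank + 2:
        raise ValueError("need n >= latent_rank + 2 and latent_rank >= 1")
    if n_informative < latent_rank:
        raise ValueError("need at least latent_rank informative descriptors")
    if min(n_noise, n_corr_blocks, block_size, n_constant) < 0 or block_size == 1:
        raise ValueError("counts must be non-negative and blocks need >= 2 members")
    rng = np.random.default_rng(seed)

    Z = rng.standard_normal((n, latent_rank))
    beta = rng.standard_normal(latent_rank)
    beta /= np.linalg.norm(beta)
    y = Z @ beta + noise_sd * rng.standard_normal(n)

    cols: dict[str, np.ndarray] = {}
    L = rng.standard_normal((latent_rank, n_informative))
    L *= rng.uniform(0.5, 1.5, size=n_informative) / np.linalg.norm(L, axis=0)
    informative = [f"inf_{j + 1:02d}" for j in range(n_informative)]
    for j, name in enumerate(informative):
        cols[name] = Z @ L[:, j]
    noise = [f"noise_{j + 1:03d}" for j in range(n_noise)]
    for name in noise:
        cols[name] = rng.standard_normal(n)
    block_map: dict[str, list[str]] = {}
    for b in range(n_corr_blocks):
        base = rng.standard_normal(n)
        members = [f"blk{b + 1}_{i + 1}" for i in range(block_size)]
        block_map[f"blk{b + 1}"] = members
        for name in members:
            cols[name] = base + 0.1 * rng.standard_normal(n)
    constant = [f"const_{j + 1:02d}" for j in range(n_constant)]
    for name in constant:
        cols[name] = np.full(n, rng.standard_normal())

    order = rng.permutation(list(cols))
    ids = [f"C{i + 1:03d}" for i in range(n)]
    X = pd.DataFrame({name: cols[name] for name in order}, index=ids)
    truth = SyntheticTruth(
        informative_names=informative,
        noise_names=noise,
        correlated_block_map=block_map,
        constant_names=constant,
        latent_rank=latent_rank,
        noise_sd=noise_sd,
        seed=seed,
    )
    return X, pd.Series(y, index=ids, name="y"), truth
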