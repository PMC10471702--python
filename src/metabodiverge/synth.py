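"""Synthetic plasma-metabolome panels for two divergently selected lines.

The generator emulates an untargeted LC-MS/MS plasma metabolome of two
rabbit lines divergently selected for intramuscular fat (IMF) content:
four acquisition blocks (positive-early, positive-late, negative, polar),
log-normal compositional abundances, per-metabolite zero inflation, a
planted subset of line-affected metabolites with effects expressed in
units of the metabolite's log-scale standard deviation, and an IMF
phenotype shifted between lines.

Every downstream stage of the pipeline is testable against the planted
truth recorded by the generator.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

BLOCKS = ("positive-early", "positive-late", "negative", "polar")

#: Retained metabolite counts per acquisition block in the motivating study.
DEFAULT_BLOCK_SIZES = (242, 168, 399, 111)


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic metabolome generator.

    Attributes
    ----------
    n_per_line:
        Samples per line (H and L). Must be even so that sexes balance.
    n_metabolites_per_block:
        Metabolite count for each of the four acquisition blocks.
    frac_affected:
        Fraction of metabolites with a planted between-line effect.
    effect_size_range:
        Planted |effect| range, in units of the metabolite's log-scale SD.
    zero_rate_range:
        Range from which each metabolite's per-line zero (non-detection)
        rate is drawn uniformly, independently per line.
    imf_base:
        Mean IMF of the L line, g IMF / 100 g fresh muscle.
    imf_line_gap:
        H-minus-L difference in mean IMF, g/100 g.
    imf_noise_sd:
        Residual SD of IMF within line, g/100 g.
    latent_rank:
        Rank of an optional shared latent factor structure inducing
        inter-metabolite correlation (0 = independent metabolites).
    latent_sd:
        Log-scale SD contributed by each latent factor when latent_rank > 0.
    seed:
        Master seed; all internal streams are spawned from it.
    """

    n_per_line: int = 24
    n_metabolites_per_block: tuple[int, int, int, int] = DEFAULT_BLOCK_SIZES
    frac_affected: float = 0.35
    effect_size_range: tuple[float, float] = (0.23, 6.04)
    zero_rate_range: tuple[float, float] = (0.0, 0.15)
    imf_base: float = 0.84
    imf_line_gap: float = 0.45
    imf_noise_sd: float = 0.145
    latent_rank: int = 0
    latent_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_line <= 0:
            raise ValueError("n_per_line must be positive")
        if self.n_per_line % 2:
            raise ValueError("n_per_line must be even (sex-balanced design)")
        if len(self.n_metabolites_per_block) != 4:
            raise ValueError("need exactly four block sizes")
        if any(m <= 0 for m in self.n_metabolites_per_block):
            raise ValueError("block sizes must be positive")
        if not 0.0 <= self.frac_affected <= 1.0:
            raise ValueError("frac_affected must lie in [0, 1]")
        lo, hi = self.effect_size_range
        if lo > hi or lo < 0:
            raise ValueError("effect_size_range must be 0 <= lo <= hi")
        zlo, zhi = self.zero_rate_range
        if not (0.0 <= zlo <= zhi <= 1.0):
            raise ValueError("zero_rate_range must lie within [0, 1]")
        if self.latent_rank < 0:
            raise ValueError("latent_rank must be >= 0")

    @property
    def n_metabolites(self) -> int:
        return int(sum(self.n_metabolites_per_block))


@dataclass
class MetabolomePanel:
    """A samples x metabolites abundance matrix with study annotations.

    ``abundance`` holds non-negative intensities (0 = not detected);
    ``samples`` carries line (H/L), sex (M/F) and the IMF phenotype;
    ``blocks`` maps every metabolite to its acquisition block. When the
    panel is synthetic, ``truth`` records the planted per-metabolite
    line effect in SD units (0 for unaffected metabolites) and
    ``original`` the pre-missingness abundances, so imputation can be
    benchmarked against ground truth.
    """

    abundance: pd.DataFrame
    samples: pd.DataFrame
    blocks: pd.Series
    truth: pd.Series | None = None
    original: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if (self.abundance.values < 0).any():
            raise ValueError("abundances must be non-negative")
        if not self.abundance.index.equals(self.samples.index):
            raise ValueError("abundance rows and sample metadata must align")
        for col in ("line", "sex", "imf"):
            if col not in self.samples.columns:
                raise ValueError(f"sample metadata lacks column {col!r}")
        if not set(self.samples["line"]).issubset({"H", "L"}):
            raise ValueError("line labels must be H or L")
        if not self.abundance.columns.equals(self.blocks.index):
            raise ValueError("block assignment must cover all metabolites exactly once")
        unknown = set(self.blocks) - set(BLOCKS)
        if unknown:
            raise ValueError(f"unknown acquisition blocks: {sorted(unknown)}")

    @property
    def n_samples(self) -> int:
        return self.abundance.shape[0]

    @property
    def n_metabolites(self) -> int:
        return self.abundance.shape[1]

    @property
    def line_of(self) -> pd.Series:
        return self.samples["line"]

    @property
    def sex_of(self) -> pd.Series:
        return self.samples["sex"]

    @property
    def imf_of(self) -> pd.Series:
        return self.samples["imf"]

    def subset_metabolites(self, keep: list[str] | pd.Index) -> "MetabolomePanel":
        keep = pd.Index(keep)
        return MetabolomePanel(
            abundance=self.abundance.loc[:, keep].copy(),
            samples=self.samples.copy(),
            blocks=self.blocks.loc[keep].copy(),
            truth=None if self.truth is None else self.truth.loc[keep].copy(),
            original=None if self.original is None else self.original.loc[:, keep].copy(),
        )

    def split_blocks(self) -> dict[str, "MetabolomePanel"]:
        """Partition the panel into one sub-panel per acquisition block."""
        out = {}
        for block in BLOCKS:
            cols = self.blocks.index[self.blocks == block]
            if len(cols):
                out[block] = self.subset_metabolites(cols)
        return out

    # -- disk round-trip ---------------------------------------------------

    def write(self, directory: str | Path) -> None:
        """Write abundance + metadata CSVs (and a JSON truth file if present)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.abundance.to_csv(directory / "abundance.csv", index_label="sample_id")
        meta = self.samples.copy()
        meta.to_csv(directory / "metadata.csv", index_label="sample_id")
        self.blocks.rename("block").to_csv(directory / "blocks.csv", index_label="metabolite_id")
        if self.truth is not None:
            payload = {"planted_effect_sd": self.truth.round(10).to_dict()}
            (directory / "truth.json").write_text(json.dumps(payload, indent=1))

    @classmethod
    def read(cls, directory: str | Path) -> "MetabolomePanel":
        directory = Path(directory)
        abundance = pd.read_csv(directory / "abundance.csv", index_col="sample_id")
        abundance.columns.name = "metabolite_id"
        samples = pd.read_csv(directory / "metadata.csv", index_col="sample_id")
        blocks = pd.read_csv(directory / "blocks.csv", index_col="metabolite_id")["block"]
        truth = None
        truth_path = directory / "truth.json"
        if truth_path.exists():
            payload = json.loads(truth_path.read_text())
            truth = pd.Series(payload["planted_effect_sd"], name="planted_effect_sd")
            truth = truth.reindex(abundance.columns)
        return cls(abundance=abundance, samples=samples, blocks=blocks, truth=truth)


def _spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Derive independent child generators from one master seed.

    Stream splitting uses :class:`numpy.random.SeedSequence` spawning so
    that each pipeline stage consumes its own stream: re-running one stage
    never perturbs another.
    """
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(child) for child in ss.spawn(n)]


def _sample_frame(config: SynthConfig) -> pd.DataFrame:
    half = config.n_per_line // 2
    rows = []
    for line in ("H", "L"):
        for i in range(config.n_per_line):
            sex = "M" if i < half else "F"
            rows.append({"sample_id": f"{line}{i + 1:02d}", "line": line, "sex": sex})
    return pd.DataFrame(rows).set_index("sample_id")


def generate_panel(config: SynthConfig) -> MetabolomePanel:
    """Generate a synthetic two-line metabolome panel.

    Log-abundances are Gaussian per metabolite. A planted metabolite j
    receives a between-line log-mean shift of effect_j * sigma_j, i.e. the
    effect is expressed in units of the metabolite's residual log-scale SD,
    split symmetrically (+-effect/2) around the grand mean so that the H
    minus L log-mean difference equals the recorded truth. Zeros
    (non-detections) are then injected per metabolite at a rate drawn
    uniformly from ``zero_rate_range``, independently for each line. The
    IMF phenotype is ``imf_base + 1{line=H} * imf_line_gap + N(0, imf_noise_sd)``;
    its coupling to the planted metabolites arises through the shared line
    effect, as in a divergent-selection design.
    """
    rng_struct, rng_abund, rng_zero, rng_imf = _spawn_rngs(config.seed, 4)

    samples = _sample_frame(config)
    n = len(samples)
    p = config.n_metabolites

    met_ids, block_names = [], []
    short = {"positive-early": "PE", "positive-late": "PL", "negative": "NEG", "polar": "POL"}
    for block, size in zip(BLOCKS, config.n_metabolites_per_block):
        for j in range(size):
            met_ids.append(f"{short[block]}_{j + 1:04d}")
            block_names.append(block)
    blocks = pd.Series(block_names, index=pd.Index(met_ids, name="metabolite_id"), name="block")

    # per-metabolite baselines: log-mean and log-SD of intensity
    mu = rng_struct.normal(12.0, 2.0, size=p)
    sigma = rng_struct.uniform(0.2, 0.8, size=p)

    n_affected = int(round(config.frac_affected * p))
    affected = rng_struct.choice(p, size=n_affected, replace=False)
    lo, hi = config.effect_size_range
    effects = np.zeros(p)
    if n_affected:
        magnitudes = rng_struct.uniform(lo, hi, size=n_affected)
        signs = rng_struct.choice([-1.0, 1.0], size=n_affected)
        effects[affected] = magnitudes * signs

    line_code = (samples["line"] == "H").to_numpy(float) - 0.5  # H=+1/2, L=-1/2
    log_x = (
        mu[None, :]
        + line_code[:, None] * (effects * sigma)[None, :]
        + rng_abund.normal(size=(n, p)) * sigma[None, :]
    )
    if config.latent_rank > 0:
        scores = rng_abund.normal(size=(n, config.latent_rank))
        loadings = rng_abund.normal(size=(config.latent_rank, p))
        loadings /= np.linalg.norm(loadings, axis=1, keepdims=True)
        log_x += config.latent_sd * scores @ loadings

    abundance = pd.DataFrame(np.exp(log_x), index=samples.index, columns=blocks.index)

    imf = (
        config.imf_base
        + (samples["line"] == "H").to_numpy(float) * config.imf_line_gap
        + rng_imf.normal(0.0, config.imf_noise_sd, size=n)
    )
    samples = samples.assign(imf=imf)

    truth = pd.Series(effects, index=blocks.index, name="planted_effect_sd")
    panel = MetabolomePanel(
        abundance=abundance, samples=samples, blocks=blocks, truth=truth, original=None
    )

    # per-metabolite, per-line non-detection rates
    zlo, zhi = config.zero_rate_range
    rates = pd.DataFrame(
        rng_struct.uniform(zlo, zhi, size=(p, 2)), index=blocks.index, columns=["H", "L"]
    )
    zero_seed = int(rng_zero.integers(0, 2**31 - 1))
    return inject_missingness(panel, rates, seed=zero_seed)


def inject_missingness(
    panel: MetabolomePanel,
    rates: pd.Series | pd.DataFrame | float,
    seed: int,
) -> MetabolomePanel:
    """Zero out cells by independent Bernoulli draws, emulating non-detection.

    ``rates`` may be a scalar, a per-metabolite Series, or a DataFrame with
    one column per line (per-metabolite, per-line rates). The original
    abundances are kept on the returned panel so imputation accuracy can be
    measured against them.
    """
    p = panel.n_metabolites
    if np.isscalar(rates):
        rates = pd.DataFrame(
            np.full((p, 2), float(rates)), index=panel.abundance.columns, columns=["H", "L"]
        )
    elif isinstance(rates, pd.Series):
        rates = pd.DataFrame({"H": rates, "L": rates})
    rates = rates.reindex(panel.abundance.columns)
    if rates.isna().any().any():
        raise ValueError("rates must cover every metabolite")
    if ((rates < 0) | (rates > 1)).any().any():
        raise ValueError("zero rates must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    values = panel.abundance.to_numpy(copy=True)
    line = panel.line_of.to_numpy()
    for ln in ("H", "L"):
        rows = line == ln
        if not rows.any():
            continue
        u = rng.random(size=(int(rows.sum()), p))
        mask = u < rates[ln].to_numpy()[None, :]
        block_vals = values[rows]
        block_vals[mask] = 0.0
        values[rows] = block_vals

    abundance = pd.DataFrame(values, index=panel.abundance.index, columns=panel.abundance.columns)
    original = panel.original if panel.original is not None else panel.abundance.copy()
    return MetabolomePanel(
        abundance=abundance,
        samples=panel.samples.copy(),
        blocks=panel.blocks.copy(),
        truth=None if panel.truth is None else panel.truth.copy(),
        original=original,
    )
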