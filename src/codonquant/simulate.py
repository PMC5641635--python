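"""Synthetic proteome + TMT quantification simulator with known ground truth.

Generates an in-frame coding-sequence database, digests its translations into
tryptic peptides, and emits a PSM-level reporter-quantification table for a
10-plex style two-group design (n control vs n knockout channels), together
with a truth table recording every protein's true abundance, true log2 fold
change and its Lys(AAA) codon frequency.

The injected group effect is linear on the log2 scale in the protein's
AAA frequency (percent): ``true_log2fc = -effect_beta * f_AAA_percent``.
``effect_beta = 0`` yields an exact null; larger values let downstream
statistics be exercised for power/recovery.

All randomness flows from a single ``numpy.random.Generator`` seeded with
``SimulationConfig.seed``; identical config + seed is byte-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .genetics import CODON_INDEX, SENSE_CODONS, translate

__all__ = [
    "SimulationConfig",
    "CodingSequence",
    "SampleDesign",
    "generate_coding_sequences",
    "translate_cds",
    "digest_protein",
    "simulate_quant_experiment",
    "simulate_dataset",
    "uniform_codon_usage",
    "mammalian_codon_usage",
]

# score model for the opaque search-engine score: targets are stochastically
# higher than reversed-sequence decoys
TARGET_SCORE_MEAN = 3.0
DECOY_SCORE_MEAN = 1.5
SCORE_SD = 0.8


def uniform_codon_usage() -> dict[str, float]:
    """Equal weight on each of the 61 sense codons (the testable default)."""
    return {c: 1.0 for c in SENSE_CODONS}


# Approximate mammalian relative codon weights (per-thousand scale,
# rounded); an optional, more realistic alternative to the uniform table.
_MAMMALIAN_USAGE = {
    "TTT": 17.2, "TTC": 21.8, "TTA": 6.7, "TTG": 13.4, "CTT": 13.4,
    "CTC": 20.2, "CTA": 8.1, "CTG": 39.5, "ATT": 15.4, "ATC": 22.5,
    "ATA": 7.4, "ATG": 22.8, "GTT": 10.7, "GTC": 15.4, "GTA": 7.4,
    "GTG": 28.4, "TCT": 16.2, "TCC": 18.1, "TCA": 11.8, "TCG": 4.2,
    "CCT": 18.4, "CCC": 18.2, "CCA": 17.3, "CCG": 6.2, "ACT": 13.7,
    "ACC": 19.0, "ACA": 16.0, "ACG": 5.6, "GCT": 20.0, "GCC": 26.0,
    "GCA": 15.8, "GCG": 6.4, "TAT": 12.2, "TAC": 16.1, "CAT": 10.6,
    "CAC": 15.3, "CAA": 12.0, "CAG": 34.1, "AAT": 15.6, "AAC": 20.3,
    "AAA": 21.9, "AAG": 33.6, "GAT": 21.0, "GAC": 26.0, "GAA": 27.0,
    "GAG": 39.4, "TGT": 11.4, "TGC": 12.3, "TGG": 12.5, "CGT": 4.7,
    "CGC": 9.4, "CGA": 6.6, "CGG": 10.2, "AGT": 12.7, "AGC": 19.7,
    "AGA": 12.1, "AGG": 12.2, "GGT": 11.4, "GGC": 21.2, "GGA": 16.8,
    "GGG": 15.2,
}


def mammalian_codon_usage() -> dict[str, float]:
    """Approximate mammalian codon weights over the 61 sense codons."""
    return dict(_MAMMALIAN_USAGE)


@dataclass
class SimulationConfig:
    """Knobs for the synthetic proteome and quantification experiment.

    Lengths are drawn log-normally with the given mean/sd on the amino-acid
    scale. ``codon_dispersion`` is the total Dirichlet concentration used to
    perturb ``codon_usage`` per protein so that f_AAA varies across proteins
    (smaller = more dispersion).
    """

    n_proteins: int = 300
    length_mean_aa: float = 80.0
    length_sd_aa: float = 25.0
    codon_usage: Mapping[str, float] = field(default_factory=uniform_codon_usage)
    codon_dispersion: float = 6.0
    n_control: int = 5
    n_ko: int = 5
    effect_beta: float = 0.0
    peptide_noise_sd: float = 1.0
    psm_per_peptide_mean: float = 1.0
    channel_dropout_p: float = 0.05
    decoy_fraction: float = 0.1
    base_sn_mean: float = 20.0
    no_ms3_p: float = 0.02
    protein_abundance_sd_log: float = 1.0
    max_missed_cleavages: int = 2
    min_peptide_len: int = 6
    max_peptide_len: int = 40
    channel_scale: Sequence[float] | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_proteins <= 0:
            raise ConfigurationError("n_proteins must be positive")
        if self.length_mean_aa <= 0 or self.length_sd_aa <= 0:
            raise ConfigurationError(
                "degenerate length distribution: mean and sd must be positive")
        if set(self.codon_usage) != set(SENSE_CODONS):
            raise ConfigurationError(
                "codon_usage keys must be exactly the 61 sense codons")
        weights = np.array([self.codon_usage[c] for c in SENSE_CODONS], float)
        if (weights < 0).any() or weights.sum() <= 0:
            raise ConfigurationError("codon_usage weights must be non-negative "
                                     "with positive total")
        if self.codon_dispersion <= 0:
            raise ConfigurationError("codon_dispersion must be positive")
        if self.n_control <= 0 or self.n_ko <= 0:
            raise ConfigurationError("both groups need at least one channel")
        for name in ("channel_dropout_p", "decoy_fraction", "no_ms3_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if self.decoy_fraction >= 1.0:
            raise ConfigurationError("decoy_fraction must be < 1")
        if self.peptide_noise_sd < 0 or self.psm_per_peptide_mean < 0:
            raise ConfigurationError("noise/PSM-rate parameters must be >= 0")
        if self.base_sn_mean <= 0:
            raise ConfigurationError("base_sn_mean must be positive")
        if self.max_missed_cleavages < 0:
            raise ConfigurationError("max_missed_cleavages must be >= 0")
        if not 0 < self.min_peptide_len <= self.max_peptide_len:
            raise ConfigurationError("need 0 < min_peptide_len <= max_peptide_len")
        n_ch = self.n_control + self.n_ko
        if self.channel_scale is not None and len(self.channel_scale) != n_ch:
            raise ConfigurationError(
                "channel_scale length must equal channel count")

    @property
    def n_channels(self) -> int:
        return self.n_control + self.n_ko

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["codon_usage"] = dict(self.codon_usage)
        if self.channel_scale is not None:
            d["channel_scale"] = list(self.channel_scale)
        return d


@dataclass(frozen=True)
class CodingSequence:
    """An in-frame, stop-free nucleotide CDS and its translation."""

    id: str
    nt_seq: str
    aa_seq: str = dataclasses.field(default="", compare=False)

    def __post_init__(self):
        aa = translate(self.nt_seq)  # validates frame + stops
        if self.aa_seq and self.aa_seq != aa:
            raise ValidationError(
                f"{self.id}: supplied aa_seq does not match translation")
        object.__setattr__(self, "aa_seq", aa)

    def __len__(self) -> int:
        return len(self.aa_seq)


@dataclass(frozen=True)
class SampleDesign:
    """Mapping of reporter channels to samples and groups."""

    channels: tuple[str, ...]
    sample_ids: tuple[str, ...]
    groups: tuple[str, ...]  # each "control" or "ko"

    def __post_init__(self):
        if len({len(self.channels), len(self.sample_ids), len(self.groups)}) != 1:
            raise ConfigurationError("design columns must have equal length")
        if len(set(self.channels)) != len(self.channels):
            raise ConfigurationError("channel ids must be unique")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ConfigurationError("sample ids must be unique")
        bad = set(self.groups) - {"control", "ko"}
        if bad:
            raise ConfigurationError(f"unknown group labels: {sorted(bad)}")
        if "control" not in self.groups or "ko" not in self.groups:
            raise ConfigurationError("both groups must be non-empty")

    @classmethod
    def default(cls, n_control: int = 5, n_ko: int = 5) -> "SampleDesign":
        n = n_control + n_ko
        channels = tuple(f"ch{i + 1:02d}" for i in range(n))
        samples = tuple(f"Ctrl{i + 1}" for i in range(n_control)) + tuple(
            f"KO{i + 1}" for i in range(n_ko))
        groups = ("control",) * n_control + ("ko",) * n_ko
        return cls(channels, samples, groups)

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def samples_in(self, group: str) -> tuple[str, ...]:
        return tuple(s for s, g in zip(self.sample_ids, self.groups) if g == group)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "channel_id": self.channels,
            "sample_id": self.sample_ids,
            "group": self.groups,
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SampleDesign":
        required = {"channel_id", "sample_id", "group"}
        if not required.issubset(df.columns):
            raise ValidationError(
                f"design table needs columns {sorted(required)}")
        return cls(tuple(df["channel_id"].astype(str)),
                   tuple(df["sample_id"].astype(str)),
                   tuple(df["group"].astype(str)))


def translate_cds(cds: CodingSequence) -> str:
    """Standard-genetic-code translation of a validated CDS."""
    return translate(cds.nt_seq)


def _base_probs(config: SimulationConfig) -> np.ndarray:
    w = np.array([config.codon_usage[c] for c in SENSE_CODONS], float)
    return w / w.sum()


def generate_coding_sequences(
        config: SimulationConfig,
        rng: np.random.Generator | None = None) -> list[CodingSequence]:
    """Generate ``n_proteins`` stop-free coding sequences.

    Each protein's codon usage is drawn from a Dirichlet centred on
    ``config.codon_usage`` with total concentration ``codon_dispersion``,
    so per-protein codon frequencies (notably f_AAA) vary. The first codon
    is always ATG; stop codons are never emitted.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    p = _base_probs(config)
    sigma2 = np.log1p((config.length_sd_aa / config.length_mean_aa) ** 2)
    mu = np.log(config.length_mean_aa) - sigma2 / 2.0
    lengths = np.maximum(
        np.rint(rng.lognormal(mu, np.sqrt(sigma2), config.n_proteins)), 10
    ).astype(int)

    support = p > 0
    alpha = config.codon_dispersion * p[support]
    codon_arr = np.array(SENSE_CODONS)
    width = len(str(config.n_proteins))
    out: list[CodingSequence] = []
    for i in range(config.n_proteins):
        usage = np.zeros_like(p)
        usage[support] = rng.dirichlet(alpha)
        idx = rng.choice(len(SENSE_CODONS), size=lengths[i] - 1, p=usage)
        nt = "ATG" + "".join(codon_arr[idx])
        out.append(CodingSequence(f"SYNP{i + 1:0{max(width, 4)}d}", nt))
    return out


def digest_protein(aa_seq: str, max_missed_cleavages: int = 2,
                   min_len: int = 6, max_len: int = 40,
                   ) -> list[tuple[str, int, int]]:
    """In-silico tryptic digest: cleave after K/R unless followed by P.

    Returns ``(peptide, start_aa_0based, missed_cleavages)`` for every
    product with at most ``max_missed_cleavages`` internal uncut sites and
    length within ``[min_len, max_len]``; coordinates are 0-based half-open.
    Ordered by start position, then missed-cleavage count.
    """
    if not aa_seq:
        raise ValidationError("aa_seq must be non-empty")
    if max_missed_cleavages < 0:
        raise ValidationError("max_missed_cleavages must be >= 0")
    # boundaries of fully-cleaved fragments
    cuts = [0]
    for i, aa in enumerate(aa_seq[:-1]):
        if aa in "KR" and aa_seq[i + 1] != "P":
            cuts.append(i + 1)
    cuts.append(len(aa_seq))

    products: list[tuple[str, int, int]] = []
    n_frag = len(cuts) - 1
    for i in range(n_frag):
        for mc in range(max_missed_cleavages + 1):
            j = i + mc + 1
            if j > n_frag:
                break
            start, end = cuts[i], cuts[j]
            if min_len <= end - start <= max_len:
                products.append((aa_seq[start:end], start, mc))
    return products


def _digest_catalog(cds_list: Sequence[CodingSequence],
                    config: SimulationConfig):
    """Unique peptides over all proteins with parent bookkeeping.

    Returns (peptides, parents) where parents[k] is the ordered list of
    (protein_index, start_aa) pairs producing peptides[k].
    """
    pep_index: dict[str, int] = {}
    peptides: list[str] = []
    parents: list[list[tuple[int, int]]] = []
    for pi, cds in enumerate(cds_list):
        for pep, start, _mc in digest_protein(
                cds.aa_seq, config.max_missed_cleavages,
                config.min_peptide_len, config.max_peptide_len):
            k = pep_index.get(pep)
            if k is None:
                pep_index[pep] = len(peptides)
                peptides.append(pep)
                parents.append([(pi, start)])
            elif parents[k][-1][0] != pi:
                parents[k].append((pi, start))
    return peptides, parents


def simulate_quant_experiment(
        cds_list: Sequence[CodingSequence],
        design: SampleDesign,
        config: SimulationConfig,
        rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emit a PSM reporter-quantification table and its ground-truth table.

    Per protein, ``true_log2fc = -effect_beta * f_AAA_percent`` applies to
    knockout channels. PSM counts per peptide are Poisson; reporter S:N is
    ``base_sn_mean * base_abundance * 2^(group effect) * 2^N(0, noise_sd)``
    per channel, with channels dropped to missing independently with
    probability ``channel_dropout_p``. Decoy PSMs come from reversed protein
    sequences (never colliding with a target peptide) with stochastically
    lower scores.
    """
    config.validate()
    if not cds_list:
        raise ConfigurationError("cds_list must be non-empty")
    if design.n_channels != config.n_channels:
        raise ConfigurationError(
            f"design has {design.n_channels} channels but config expects "
            f"{config.n_channels}")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    n_prot = len(cds_list)
    n_ch = design.n_channels
    ko_mask = np.array([g == "ko" for g in design.groups])
    scale = (np.ones(n_ch) if config.channel_scale is None
             else np.asarray(config.channel_scale, float))

    # ground truth
    aaa_idx = CODON_INDEX["AAA"]
    f_aaa = np.empty(n_prot)
    for i, cds in enumerate(cds_list):
        counts = _codon_counts_fast(cds.nt_seq)
        f_aaa[i] = 100.0 * counts[aaa_idx] / len(cds)
    base_abund = rng.lognormal(0.0, config.protein_abundance_sd_log, n_prot)
    log2fc = -config.effect_beta * f_aaa
    truth = pd.DataFrame({
        "protein_id": [c.id for c in cds_list],
        "true_base_abundance": base_abund,
        "true_log2fc": log2fc,
        "f_aaa_percent": f_aaa,
    })

    # target peptides
    peptides, parents = _digest_catalog(cds_list, config)
    n_pep = len(peptides)
    if n_pep == 0:
        raise ConfigurationError(
            "digestion produced no peptides; lengthen proteins or relax limits")
    psm_counts = rng.poisson(config.psm_per_peptide_mean, n_pep)
    rep = np.repeat(np.arange(n_pep), psm_counts)
    n_t = len(rep)
    prot_of = np.array([parents[k][0][0] for k in range(n_pep)])
    start_of = np.array([parents[k][0][1] for k in range(n_pep)])

    base = config.base_sn_mean * base_abund[prot_of[rep]]
    mult = np.where(ko_mask[None, :], 2.0 ** log2fc[prot_of[rep]][:, None], 1.0)
    noise = 2.0 ** rng.normal(0.0, config.peptide_noise_sd, (n_t, n_ch))
    sn_t = base[:, None] * mult * noise * scale[None, :]
    if config.channel_dropout_p > 0:
        sn_t[rng.random((n_t, n_ch)) < config.channel_dropout_p] = np.nan
    score_t = rng.normal(TARGET_SCORE_MEAN, SCORE_SD, n_t)
    ms3_t = (rng.random(n_t) >= config.no_ms3_p).astype(int)

    # decoys from reversed sequences, skipping any peptide seen in targets
    target_set = set(peptides)
    decoy_peps: list[tuple[str, str, int]] = []
    for cds in cds_list:
        rev = cds.aa_seq[::-1]
        for pep, start, _mc in digest_protein(
                rev, config.max_missed_cleavages,
                config.min_peptide_len, config.max_peptide_len):
            if pep not in target_set:
                decoy_peps.append((pep, f"rev_{cds.id}", start))
    f = config.decoy_fraction
    n_d = int(round(n_t * f / (1.0 - f))) if (f > 0 and decoy_peps) else 0
    if n_d:
        pick = rng.integers(0, len(decoy_peps), n_d)
        sn_d = (config.base_sn_mean
                * 2.0 ** rng.normal(0.0, config.peptide_noise_sd, (n_d, n_ch))
                * scale[None, :])
        if config.channel_dropout_p > 0:
            sn_d[rng.random((n_d, n_ch)) < config.channel_dropout_p] = np.nan
        score_d = rng.normal(DECOY_SCORE_MEAN, SCORE_SD, n_d)
        ms3_d = (rng.random(n_d) >= config.no_ms3_p).astype(int)

    rows_pep = [peptides[k] for k in rep]
    rows_prot = [";".join(cds_list[pi].id for pi, _ in parents[k]) for k in rep]
    rows_start = start_of[rep]
    records = {
        "peptide": rows_pep,
        "protein_ids": rows_prot,
        "start_aa": rows_start,
        "score": score_t,
        "is_decoy": np.zeros(n_t, int),
        "has_ms3": ms3_t,
    }
    psms = pd.DataFrame(records)
    sn_cols = [f"sn_ch{i + 1:02d}" for i in range(n_ch)]
    psms[sn_cols] = sn_t
    if n_d:
        decoys = pd.DataFrame({
            "peptide": [decoy_peps[j][0] for j in pick],
            "protein_ids": [decoy_peps[j][1] for j in pick],
            "start_aa": [decoy_peps[j][2] for j in pick],
            "score": score_d,
            "is_decoy": np.ones(n_d, int),
            "has_ms3": ms3_d,
        })
        decoys[sn_cols] = sn_d
        psms = pd.concat([psms, decoys], ignore_index=True)
    psms.insert(0, "psm_id", [f"PSM{i + 1:07d}" for i in range(len(psms))])
    return psms, truth


def _codon_counts_fast(nt_seq: str) -> np.ndarray:
    counts = np.zeros(len(SENSE_CODONS), dtype=np.int64)
    for i in range(0, len(nt_seq), 3):
        counts[CODON_INDEX[nt_seq[i:i + 3]]] += 1
    return counts


def simulate_dataset(config: SimulationConfig):
    """One-call simulation: (cds_list, design, psms, truth) from one stream."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    cds_list = generate_coding_sequences(config, rng)
    design = SampleDesign.default(config.n_control, config.n_ko)
    psms, truth = simulate_quant_experiment(cds_list, design, config, rng)
    return cds_list, design, psms, truth
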