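"""Synthetic group-structured communities with paired method read-outs.

The generator produces the latent ground truth and both measurement arms
for a study design of a few age groups whose richness rises by an order of
magnitude across groups (hundreds to thousands of taxa):

* :func:`simulate_true_communities` — per-group template communities with
  log-normal ranked abundances; each sample is a mixture of its group
  template and a sample-specific redraw, so a single knob ``theta``
  controls expected within-group Bray-Curtis similarity. Adjacent groups
  share a configurable core of taxa.
* :func:`simulate_pyrosequencing` — multinomial read sampling at a
  truncated-normal depth per sample (default 10,800 +/- 2,860 reads,
  floor 1,000).
* :func:`simulate_arisa` — each taxon carries one or (with probability
  ``p_second_length``) two intergenic-spacer fragment lengths drawn
  uniformly on the detectable window, so distinct taxa can collide on a
  length or a bin; fluorescence is gain x relative abundance per length,
  with per-replicate multiplicative intensity noise, Gaussian size-calling
  noise, and spurious low-RFU baseline peaks.

Every operation takes an explicit seed and is fully deterministic given it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import OTUTable, PeakRecord, PeakTable, READ_COUNT, SampleMetadata


@dataclass(frozen=True)
class GroupSpec:
    label: str
    n_samples: int
    richness: int
    theta: float = 0.85  # within-group similarity knob in [0, 1]


@dataclass(frozen=True)
class CommunitySpec:
    """Study design for the synthetic communities.

    Defaults follow a four-age-group design: 6/5/5/5 samples with true
    richness 200/600/2000/2400, non-decreasing along the declared order.
    ``sigma`` is the log-normal shape of the ranked abundances;
    ``shared_core_fraction`` is the fraction of the smaller adjacent
    group's taxa carried over between consecutive groups.
    """

    groups: tuple[GroupSpec, ...] = (
        GroupSpec("1-3 days", 6, 200),
        GroupSpec("2 months", 5, 600),
        GroupSpec("6 months", 5, 2000),
        GroupSpec("2 years", 5, 2400),
    )
    sigma: float = 1.5
    shared_core_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        rich = [g.richness for g in self.groups]
        if any(b < a for a, b in zip(rich, rich[1:])):
            raise ConfigError("group richness must be non-decreasing")
        for g in self.groups:
            if not (0.0 <= g.theta <= 1.0):
                raise ConfigError("theta must lie in [0, 1]")
            if g.n_samples < 1 or g.richness < 1:
                raise ConfigError("n_samples and richness must be positive")
        if not (0.0 <= self.shared_core_fraction <= 1.0):
            raise ConfigError("shared_core_fraction must lie in [0, 1]")


@dataclass
class TrueCommunity:
    """Latent per-sample relative abundances over a global taxon pool."""

    abundances: pd.DataFrame  # samples x taxa, rows sum to 1
    metadata: SampleMetadata

    @property
    def sample_ids(self) -> list[str]:
        return list(self.abundances.index)

    @property
    def n_taxa(self) -> int:
        return self.abundances.shape[1]


@dataclass(frozen=True)
class ArisaSignalModel:
    """Physical model mapping taxa to electropherogram peaks."""

    min_bp: float = 200.0
    max_bp: float = 1150.0
    p_second_length: float = 0.2   # chance of a second ribosomal operon length
    gain: float = 1e5              # RFU per unit relative abundance
    size_noise_sd: float = 0.2     # bp, size-calling error
    intensity_noise_sigma: float = 0.05  # lognormal sigma per peak per replicate
    baseline_rate: float = 20.0    # expected spurious peaks per profile
    baseline_rfu_scale: float = 5.0  # exponential scale of spurious peak RFU
    instrument_floor_rfu: float = 0.5  # peaks below this are never reported

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ConfigError("gain must be positive")
        if self.max_bp <= self.min_bp:
            raise ConfigError("invalid fragment-length window")


def _sub_rngs(seed: int | None, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_true_communities(
    spec: CommunitySpec, seed: int | None = None
) -> TrueCommunity:
    """Draw the latent communities for every sample of the design.

    Each group has a template of ``richness`` taxa with normalized
    log-normal abundances; sample i of the group is
    ``theta * template + (1 - theta) * fresh_draw`` on the same support.
    ``theta = 1`` makes all samples of a group identical.
    """
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)

    # build group supports over a growing global pool
    supports: list[np.ndarray] = []
    pool_size = 0
    prev: np.ndarray | None = None
    for g in spec.groups:
        if prev is None:
            sup = np.arange(g.richness)
            pool_size = g.richness
        else:
            n_shared = int(round(spec.shared_core_fraction * min(g.richness, prev.size)))
            shared = rng.choice(prev, size=n_shared, replace=False)
            n_new = g.richness - n_shared
            new = np.arange(pool_size, pool_size + n_new)
            pool_size += n_new
            sup = np.sort(np.concatenate([shared, new]))
        supports.append(sup)
        prev = sup

    taxa = [f"T{i:05d}" for i in range(pool_size)]
    rows = []
    sample_ids = []
    groups_of: dict[str, str] = {}
    for gi, (g, sup) in enumerate(zip(spec.groups, supports)):
        template = rng.lognormal(0.0, spec.sigma, size=sup.size)
        template /= template.sum()
        for si in range(g.n_samples):
            noise = rng.lognormal(0.0, spec.sigma, size=sup.size)
            noise /= noise.sum()
            mix = g.theta * template + (1.0 - g.theta) * noise
            row = np.zeros(pool_size)
            row[sup] = mix / mix.sum()
            sid = f"g{gi + 1}s{si + 1:02d}"
            sample_ids.append(sid)
            groups_of[sid] = g.label
            rows.append(row)
    df = pd.DataFrame(rows, index=sample_ids, columns=taxa)
    return TrueCommunity(df, SampleMetadata(groups_of))


def simulate_pyrosequencing(
    truth: TrueCommunity,
    depth_mean: float = 10_800.0,
    depth_sd: float = 2_860.0,
    min_depth: int = 1_000,
    seed: int | None = None,
) -> OTUTable:
    """Multinomial read counts per sample at a truncated-normal depth."""
    if depth_mean <= 0:
        raise ConfigError("depth_mean must be positive")
    rng = np.random.default_rng(seed)
    counts = np.zeros(truth.abundances.shape, dtype=np.int64)
    P = truth.abundances.to_numpy()
    for i in range(P.shape[0]):
        depth = 0
        while depth < min_depth:
            depth = int(round(rng.normal(depth_mean, depth_sd)))
        counts[i] = rng.multinomial(depth, P[i])
    df = pd.DataFrame(counts, index=truth.sample_ids,
                      columns=truth.abundances.columns)
    return OTUTable(df, READ_COUNT)


def _draw_taxon_lengths(
    n_taxa: int, model: ArisaSignalModel, rng: np.random.Generator
) -> list[np.ndarray]:
    """One or two spacer lengths per taxon, uniform on the window."""
    primary = rng.uniform(model.min_bp, model.max_bp, size=n_taxa)
    second_mask = rng.random(n_taxa) < model.p_second_length
    secondary = rng.uniform(model.min_bp, model.max_bp, size=n_taxa)
    out = []
    for i in range(n_taxa):
        if second_mask[i]:
            out.append(np.array([primary[i], secondary[i]]))
        else:
            out.append(np.array([primary[i]]))
    return out


def simulate_arisa(
    truth: TrueCommunity,
    model: ArisaSignalModel = ArisaSignalModel(),
    replicates: int = 2,
    seed: int | None = None,
) -> PeakTable:
    """Emit a size-called peak table for every sample x technical replicate.

    Taxa sharing an identical fragment length merge into one peak with
    summed intensity before noise is applied; near-identical lengths are
    left for the downstream binning step to merge. Peaks below the
    instrument floor are not reported (the 10 RFU analysis filter is much
    higher and applied downstream).
    """
    rng_len, rng_sig = _sub_rngs(seed, 2)
    lengths = _draw_taxon_lengths(truth.n_taxa, model, rng_len)

    records: list[PeakRecord] = []
    P = truth.abundances.to_numpy()
    for i, sid in enumerate(truth.sample_ids):
        support = np.nonzero(P[i])[0]
        # deterministic aggregation: true length -> emitted intensity
        signal: dict[float, float] = {}
        for t in support:
            for L in lengths[t]:
                signal[float(L)] = signal.get(float(L), 0.0) + model.gain * P[i, t]
        true_sizes = sorted(signal)
        for rep in range(1, replicates + 1):
            rep_id = f"rep{rep}"
            for L in true_sizes:
                inten = signal[L] * rng_sig.lognormal(0.0, model.intensity_noise_sigma)
                if inten < model.instrument_floor_rfu:
                    continue
                size = L + rng_sig.normal(0.0, model.size_noise_sd)
                size = float(np.clip(size, 1.0, None))
                records.append(PeakRecord(sid, rep_id, size, float(inten)))
            n_noise = rng_sig.poisson(model.baseline_rate)
            noise_sizes = rng_sig.uniform(model.min_bp, model.max_bp, size=n_noise)
            noise_rfu = rng_sig.exponential(model.baseline_rfu_scale, size=n_noise)
            for size, inten in zip(noise_sizes, noise_rfu):
                if inten >= model.instrument_floor_rfu:
                    records.append(PeakRecord(sid, rep_id, float(size), float(inten)))
    return PeakTable(records, provenance="simulated")


def simulate_dataset(
    spec: CommunitySpec = CommunitySpec(),
    model: ArisaSignalModel = ArisaSignalModel(),
    depth_mean: float = 10_800.0,
    depth_sd: float = 2_860.0,
    replicates: int = 2,
    seed: int | None = None,
) -> dict:
    """Generate the full paired dataset: truth, reads, peaks, metadata."""
    s_truth, s_pyro, s_arisa = (
        int(s.generate_state(1)[0] & 0x7FFFFFFF)
        for s in np.random.SeedSequence(seed).spawn(3)
    )
    truth = simulate_true_communities(spec, seed=s_truth)
    pyro = simulate_pyrosequencing(
        truth, depth_mean=depth_mean, depth_sd=depth_sd, seed=s_pyro
    )
    peaks = simulate_arisa(truth, model, replicates=replicates, seed=s_arisa)
    return {
        "truth": truth,
        "pyro": pyro,
        "peaks": peaks,
        "metadata": truth.metadata,
    }
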