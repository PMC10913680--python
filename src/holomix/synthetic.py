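"""Seeded generator of multi-block, multi-class data with planted structure.

Each sample carries a latent factor vector: its class mean — classes sit on
a simplex with equal pairwise distances of ``class_separation`` in factor
space (standard-normal factor noise, so separation is in noise-sd units) —
plus standard normal noise. Every block loads sparsely on those shared factors: only its
``n_informative`` features carry signal, with loading magnitudes scaled by
the block's ``loading_strength``. Continuous blocks add Gaussian noise;
count blocks draw multinomial samples of ``library_size`` reads with
per-sample probabilities softmax(factors @ loadings').

The informative feature ids per block are the planted truth, reproducible
without generating data (:func:`planted_truth`). Structure (which features
are informative, their loadings) and sampling noise use separate seed
streams, so the truth is stable while the data vary with replicate draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import MetadataTable, OmicsDataset, ValidationError

_PALETTE = ["#1b9e77", "#d95f02", "#7570b3", "#e7298a",
            "#66a61e", "#e6ab02", "#a6761d", "#666666"]


@dataclass
class BlockSpec:
    name: str
    p: int
    kind: str = "continuous"      # continuous | counts
    n_informative: int = 5
    loading_strength: float = 1.0
    noise_sd: float = 1.0
    microbiome: bool | None = None   # default: counts -> True
    library_size: int | None = None  # default: the spec-level value
    abundance_sd: float = 0.0        # log-scale baseline spread (counts only):
                                     # > 0 gives the skewed taxon-abundance
                                     # profile of real ASV tables, with many
                                     # rare features

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "counts"):
            raise ValidationError(f"unknown block kind {self.kind!r}")
        if not 0 <= self.n_informative <= self.p:
            raise ValidationError("n_informative must lie in [0, p]")
        if self.loading_strength < 0 or self.noise_sd < 0:
            raise ValidationError("strength and noise sd must be >= 0")
        if self.microbiome is None:
            self.microbiome = self.kind == "counts"


@dataclass
class SyntheticSpec:
    classes: int = 4
    n_per_class: int = 3
    blocks: list = field(default_factory=list)
    shared_factors: int = 1
    class_separation: float = 3.0
    library_size: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.classes < 2 or self.n_per_class < 1 or self.shared_factors < 1:
            raise ValidationError("invalid synthetic specification")
        self.blocks = [b if isinstance(b, BlockSpec) else BlockSpec(**b)
                       for b in self.blocks]


def _simplex_means(K: int, m: int) -> np.ndarray:
    """K class means with unit pairwise distances, embedded in m dims
    (coordinates beyond K-1 are zero; m < K-1 truncates)."""
    # K standard basis vectors scaled to pairwise distance 1, centered
    E = np.eye(K) / np.sqrt(2.0)
    E -= E.mean(axis=0)
    # rotate into K-1 dims via SVD, then pad/truncate to m
    U, S, _ = np.linalg.svd(E, full_matrices=False)
    coords = U * S
    out = np.zeros((K, m))
    d = min(m, K)
    out[:, :d] = coords[:, :d]
    return out


def _streams(seed: int):
    ss = np.random.SeedSequence(seed)
    structure, noise = ss.spawn(2)
    return np.random.default_rng(structure), np.random.default_rng(noise)


def planted_truth(spec: SyntheticSpec) -> dict:
    """Informative feature ids per block; deterministic companion of
    :func:`generate_multiomics` (same structure stream, no data drawn)."""
    rng, _ = _streams(spec.seed)
    truth = {}
    for blk in spec.blocks:
        idx = np.sort(rng.choice(blk.p, size=blk.n_informative, replace=False))
        rng.normal(size=(blk.n_informative, spec.shared_factors))  # loading draw
        rng.integers(0, 2, size=blk.n_informative)                 # sign draw
        if blk.kind == "counts":
            rng.normal(size=blk.p)                                 # baseline draw
        truth[blk.name] = [f"{blk.name}_f{j + 1}" for j in idx]
    return truth


def _block_loadings(blk: BlockSpec, m: int, rng):
    idx = np.sort(rng.choice(blk.p, size=blk.n_informative, replace=False))
    raw = rng.normal(size=(blk.n_informative, m))
    signs = rng.integers(0, 2, size=blk.n_informative) * 2 - 1
    # magnitudes bounded away from zero so every planted feature is recoverable
    mag = 0.5 + np.abs(raw)
    L = np.zeros((blk.p, m))
    L[idx] = blk.loading_strength * signs[:, None] * mag / np.sqrt(m)
    return L, idx


def generate_multiomics(spec: SyntheticSpec
                        ) -> tuple[list[OmicsDataset], MetadataTable, dict]:
    """Draw one multi-block dataset; returns (blocks, metadata, truth)."""
    if not spec.blocks:
        raise ValidationError("specification lists no blocks")
    rng_struct, rng_noise = _streams(spec.seed)
    K, npc, m = spec.classes, spec.n_per_class, spec.shared_factors
    n = K * npc
    class_names = [f"C{k + 1}" for k in range(K)]
    labels = np.repeat(class_names, npc)
    sample_ids = [f"{c}_r{i + 1}" for c in class_names for i in range(npc)]
    means = spec.class_separation * _simplex_means(K, m)
    factors = means[np.repeat(np.arange(K), npc)] + rng_noise.normal(size=(n, m))

    datasets, truth = [], {}
    for blk in spec.blocks:
        L, idx = _block_loadings(blk, m, rng_struct)
        truth[blk.name] = [f"{blk.name}_f{j + 1}" for j in idx]
        signal = factors @ L.T
        if blk.kind == "continuous":
            mat = signal + blk.noise_sd * rng_noise.normal(size=(n, blk.p))
        else:
            baseline = blk.abundance_sd * rng_struct.normal(size=blk.p)
            logits = signal + baseline
            logits -= logits.max(axis=1, keepdims=True)
            probs = np.exp(logits)
            probs /= probs.sum(axis=1, keepdims=True)
            lib = blk.library_size or spec.library_size
            mat = np.vstack([rng_noise.multinomial(lib, probs[i])
                             for i in range(n)]).astype(float)
        df = pd.DataFrame(mat, index=sample_ids,
                          columns=[f"{blk.name}_f{j + 1}" for j in range(blk.p)])
        datasets.append(OmicsDataset(
            name=blk.name, values=df, is_microbiome=blk.microbiome,
            provenance=[{"operation": "simulate",
                         "parameters": {"seed": spec.seed, "kind": blk.kind,
                                        "n_informative": blk.n_informative,
                                        "loading_strength": blk.loading_strength}}]))
    metadata = MetadataTable(
        sample_to_class=dict(zip(sample_ids, labels)),
        class_to_color={c: _PALETTE[k % len(_PALETTE)]
                        for k, c in enumerate(class_names)})
    return datasets, metadata, truth


def case_study_spec(seed: int = 0) -> SyntheticSpec:
    """A fixture shaped like the sugar-beet case study: 4 varieties x 3
    replicates; normalized metabolite quantities (23 features), 16S (4,398)
    and ITS (3,252) raw ASV count tables, and a raw read-count
    transcriptomics table of 27,964 features — deliberately over the
    10,000-feature cap, and a count block that is *not* treated as
    microbiome (no compositional transform, only the cap)."""
    return SyntheticSpec(
        classes=4, n_per_class=3, shared_factors=2, library_size=50_000,
        seed=seed,
        blocks=[
            BlockSpec("metabolomics", p=23, kind="continuous",
                      n_informative=10, loading_strength=2.0, noise_sd=1.0),
            BlockSpec("16S", p=4_398, kind="counts", abundance_sd=2.5,
                      n_informative=60, loading_strength=2.0),
            BlockSpec("ITS", p=3_252, kind="counts", abundance_sd=2.5,
                      n_informative=40, loading_strength=2.0),
            BlockSpec("transcriptomics", p=27_964, kind="counts",
                      microbiome=False, library_size=2_000_000,
                      abundance_sd=1.5, n_informative=100,
                      loading_strength=2.0),
        ])
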