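"""Synthetic methylRAD data with planted structure.

The generator emulates the study design the pipeline targets: ~30 sampling
sites with 9-10 individuals each, integer tag counts at two motif contexts
(CCGG and the non-CpG CCWGG), and library sizes in the millions of reads.
Two orthogonal structures can be planted at once:

* **site clusters** — sites fall into latent clusters and a minority of
  informative markers is hypermethylated in one cluster each;
* **latent states** — individuals within every site are assigned to latent
  methylation states that cross-cut geography, with their own informative
  markers, reproducing the situation where de novo methylation groups do
  not follow sampling sites.

Counts are negative-binomial (overdispersed) around
``baseline x multiplier x library factor`` with excess zeros from a dropout
probability; informative markers are preferentially given the CCWGG motif.
Everything is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .io import MethylRadCounts, SampleMetadata, write_counts

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "generate",
    "write_fixture",
    "synthetic_annotation",
    "read_manifest",
]


@dataclass
class SyntheticConfig:
    """Generator settings; defaults mirror the emulated study design.

    ``effect_size`` is the log2 fold change of an informative marker's mean
    between its own cluster/state and the rest.  Real methylomes show a
    continuum of differentiation, so two tiers are planted: a small strongly
    informative set (``fraction_informative`` at ``effect_size``) and a
    larger weakly differentiated background (``fraction_weak`` at
    ``weak_effect_size``) that is detectable at study sample sizes but
    contributes little assignment accuracy.  ``dispersion`` is the
    negative-binomial shape (smaller = more overdispersed).  Library sizes
    are log-normal; the default meanlog puts them near 2.7M reads.
    """

    n_sites: int = 30
    individuals_per_site: int = 10
    n_markers: int = 5000
    fraction_informative: float = 0.01
    fraction_weak: float = 0.08
    weak_effect_size: float = 2.5
    n_site_clusters: int = 5
    n_latent_states: int = 1  # 1 disables within-site state structure
    effect_size: float = 2.0  # log2 fold change
    dispersion: float = 0.8
    baseline_mean: float = 5.0
    library_meanlog: float = 14.8  # exp(14.8) ~ 2.7M reads
    library_sdlog: float = 0.3
    ccwgg_fraction: float = 0.516
    ccwgg_informative_fraction: float = 0.7
    dropout: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fraction_informative", "fraction_weak", "ccwgg_fraction",
                     "ccwgg_informative_fraction", "dropout"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must be in [0, 1]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.n_sites < 1 or self.individuals_per_site < 1 or self.n_markers < 1:
            raise ValueError("need at least one site, individual and marker")


@dataclass
class SyntheticTruth:
    """Planted structure for recovery tests.

    ``cluster_informative`` / ``state_informative`` hold the strongly
    informative tier; the ``weak_*`` dicts hold the weakly differentiated
    background.  ``multipliers`` records each planted marker's mean
    multiplier in its own cluster/state.
    """

    site_cluster: dict[str, int]  # site -> cluster
    latent_state: dict[str, int]  # individual -> state
    cluster_informative: dict[str, int]  # marker -> its elevated cluster
    state_informative: dict[str, int]  # marker -> its elevated state
    weak_cluster_informative: dict[str, int] = field(default_factory=dict)
    weak_state_informative: dict[str, int] = field(default_factory=dict)
    multipliers: dict[str, float] = field(default_factory=dict)

    @property
    def informative_markers(self) -> set[str]:
        """Strong-tier markers (the minimal-set ground truth)."""
        return set(self.cluster_informative) | set(self.state_informative)

    @property
    def all_planted_markers(self) -> set[str]:
        return self.informative_markers | set(self.weak_cluster_informative) | set(
            self.weak_state_informative
        )


def generate(config: SyntheticConfig) -> tuple[MethylRadCounts, SampleMetadata, SyntheticTruth]:
    rng = np.random.default_rng(config.seed)
    n_sites = config.n_sites
    n_per = config.individuals_per_site
    n_ind = n_sites * n_per
    n_mark = config.n_markers

    sites = [f"site{s + 1:02d}" for s in range(n_sites)]
    individuals = [f"{site}_ind{i + 1:02d}" for site in sites for i in range(n_per)]
    site_of = np.repeat(np.arange(n_sites), n_per)
    markers = [f"mk{j + 1:05d}" for j in range(n_mark)]

    # planted structure
    site_cluster = np.arange(n_sites) % max(config.n_site_clusters, 1)
    rng.shuffle(site_cluster)
    latent_state = (
        rng.integers(0, config.n_latent_states, size=n_ind)
        if config.n_latent_states > 1
        else np.zeros(n_ind, dtype=int)
    )

    want_cluster = config.n_site_clusters > 1
    want_state = config.n_latent_states > 1
    n_struct = int(want_cluster) + int(want_state)

    def _assign(idx: np.ndarray) -> tuple[dict[str, int], dict[str, int]]:
        """Split marker indices between the planted structures, targets cyclic."""
        c_map: dict[str, int] = {}
        s_map: dict[str, int] = {}
        if not n_struct:
            return c_map, s_map
        if want_cluster and want_state:
            split = len(idx) // 2
            c_idx, s_idx = idx[:split], idx[split:]
        elif want_cluster:
            c_idx, s_idx = idx, np.array([], int)
        else:
            c_idx, s_idx = np.array([], int), idx
        for r, j in enumerate(c_idx):
            c_map[markers[j]] = r % config.n_site_clusters
        for r, j in enumerate(s_idx):
            s_map[markers[j]] = r % config.n_latent_states
        return c_map, s_map

    n_inf = int(round(config.fraction_informative * n_mark))
    n_weak = int(round(config.fraction_weak * n_mark))
    picked = (
        rng.choice(n_mark, size=n_inf + n_weak, replace=False)
        if n_inf + n_weak
        else np.array([], int)
    )
    inf_idx, weak_idx = picked[:n_inf], picked[n_inf:]
    cluster_inf, state_inf = _assign(inf_idx)
    weak_cluster_inf, weak_state_inf = _assign(weak_idx)

    mult = 2.0 ** config.effect_size
    weak_mult = 2.0 ** config.weak_effect_size
    midx = {m: j for j, m in enumerate(markers)}
    # per-individual x marker mean multiplier
    M = np.ones((n_ind, n_mark))
    for maps, m_val in (
        ((cluster_inf, state_inf), mult),
        ((weak_cluster_inf, weak_state_inf), weak_mult),
    ):
        c_map, s_map = maps
        for mk, cl in c_map.items():
            M[site_cluster[site_of] == cl, midx[mk]] = m_val
        for mk, st in s_map.items():
            M[latent_state == st, midx[mk]] = m_val

    library_sizes = np.round(
        rng.lognormal(config.library_meanlog, config.library_sdlog, size=n_ind)
    ).astype(np.int64)
    lib_factor = library_sizes / np.exp(config.library_meanlog)

    mean = config.baseline_mean * M * lib_factor[:, None]
    shape = config.dispersion
    lam = rng.gamma(shape, mean / shape)  # NB as gamma-Poisson mixture
    counts = rng.poisson(lam).astype(np.int64)
    if config.dropout > 0:
        counts *= rng.random(counts.shape) >= config.dropout

    informative = np.zeros(n_mark, dtype=bool)
    informative[picked] = True
    is_ccwgg = np.where(
        informative,
        rng.random(n_mark) < config.ccwgg_informative_fraction,
        rng.random(n_mark) < config.ccwgg_fraction,
    )
    motif = np.where(is_ccwgg, "CCWGG", "CCGG").astype(object)

    data = MethylRadCounts(
        individuals=individuals,
        markers=markers,
        counts=counts,
        library_sizes=library_sizes,
        motif=motif,
    )
    meta = SampleMetadata(
        individuals=individuals,
        site={ind: sites[site_of[i]] for i, ind in enumerate(individuals)},
    )
    multipliers = {m: mult for m in list(cluster_inf) + list(state_inf)}
    multipliers.update(
        {m: weak_mult for m in list(weak_cluster_inf) + list(weak_state_inf)}
    )
    truth = SyntheticTruth(
        site_cluster={sites[s]: int(site_cluster[s]) for s in range(n_sites)},
        latent_state={ind: int(latent_state[i]) for i, ind in enumerate(individuals)},
        cluster_informative=cluster_inf,
        state_informative=state_inf,
        weak_cluster_informative=weak_cluster_inf,
        weak_state_informative=weak_state_inf,
        multipliers=multipliers,
    )
    return data, meta, truth


def write_fixture(
    data: MethylRadCounts,
    meta: SampleMetadata,
    truth: SyntheticTruth,
    config: SyntheticConfig,
    directory: str | Path,
) -> None:
    """Write counts.tsv / samples.tsv / markers.tsv / truth.json /
    manifest.yaml so the dataset round-trips through the I/O module and can
    be regenerated from the manifest alone."""
    import json

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_counts(
        data,
        meta,
        directory / "counts.tsv",
        directory / "samples.tsv",
        directory / "markers.tsv",
    )
    with open(directory / "truth.json", "w") as fh:
        json.dump(
            {
                "site_cluster": truth.site_cluster,
                "latent_state": truth.latent_state,
                "cluster_informative": truth.cluster_informative,
                "state_informative": truth.state_informative,
                "weak_cluster_informative": truth.weak_cluster_informative,
                "weak_state_informative": truth.weak_state_informative,
                "multipliers": truth.multipliers,
            },
            fh,
            indent=1,
        )
    with open(directory / "manifest.yaml", "w") as fh:
        yaml.safe_dump({"generator": "methylstruct.simulate", "config": asdict(config)}, fh)


def synthetic_annotation(
    data: MethylRadCounts,
    truth: SyntheticTruth,
    seed: int = 0,
    markers_per_contig: int = 200,
    n_background_terms: int = 20,
) -> tuple[dict[str, tuple[str, int]], str, dict[str, set[str]]]:
    """Synthetic genome annotation matched to a generated dataset.

    Lays markers out 1 kb apart on contigs, puts one single-exon gene around
    every marker, and builds a gene-to-term map in which the genes hosting
    each planted cluster's strong informative markers share a synthetic term
    (``TERM:cluster<c>``) on top of random background terms — so enrichment
    of a recovered characteristic-marker set should flag its cluster's term.

    Returns ``(marker coords, GFF3 text, term map)``.
    """
    rng = np.random.default_rng(seed)
    coords: dict[str, tuple[str, int]] = {}
    gff_lines = ["##gff-version 3"]
    term_map: dict[str, set[str]] = {}
    background = [f"TERM:bg{t}" for t in range(n_background_terms)]
    for j, marker in enumerate(data.markers):
        contig = f"ctg{j // markers_per_contig + 1}"
        pos = (j % markers_per_contig) * 1000 + 500
        coords[marker] = (contig, pos)
        gene = f"g_{marker}"
        start, end = pos - 100, pos + 100
        gff_lines.append(
            f"{contig}\tsynthetic\tgene\t{start}\t{end}\t.\t+\t.\tID={gene}"
        )
        gff_lines.append(
            f"{contig}\tsynthetic\texon\t{start}\t{end}\t.\t+\t.\t"
            f"ID={gene}.e1;Parent={gene}"
        )
        terms = set(rng.choice(background, size=rng.integers(1, 4), replace=False))
        cl = truth.cluster_informative.get(marker)
        if cl is not None:
            terms.add(f"TERM:cluster{cl}")
        term_map[gene] = terms
    return coords, "\n".join(gff_lines) + "\n", term_map


def read_manifest(directory: str | Path) -> SyntheticConfig:
    with open(Path(directory) / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    return SyntheticConfig(**manifest["config"])
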