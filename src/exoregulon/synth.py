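"""Synthetic bacterial genomes, planted binding sites and sequencing tracks.

The generator emulates the data a multiplexed ChIP-exo / RNA-seq study of
uncharacterized bacterial transcription factors produces: a single circularly
ignored (linear) chromosome with non-overlapping genes grouped into operons,
planted TF binding sites whose motif instances are written into the sequence,
strand-specific 5'-end coverage with paired exonuclease borders over uniform
background, a mock control built from 300-500 bp sheared fragments, RNAP and
sigma-70 (RpoD) occupancy over a configurable subset of promoters, and
negative-binomial RNA-seq counts with planted fold changes on direct targets.

Everything is a pure function of (parameters, seed): child RNG streams are
derived from the top-level seed by fixed component labels, so adding one
component never perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .peaks import StrandCoverage

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

# fixed child-stream labels: adding a component never reseeds the others
_STREAMS = {
    "genome": 11,
    "sites": 12,
    "exo": 13,
    "mock": 14,
    "occupancy": 15,
    "rnaseq": 16,
    "scenario": 17,
}


def child_rng(seed: int, component: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[component],)))


@dataclass
class GenomeSpec:
    length: int = 1_000_000
    n_genes: int = 800
    min_gene_len: int = 300
    max_gene_len: int = 1500
    min_intergenic: int = 60
    gc: float = 0.51
    cog_categories: tuple = ("C", "E", "G", "J", "K", "L", "M", "O", "P", "T", "S")
    operon_prob: float = 0.25


@dataclass
class ReadModel:
    """Geometry and depth of the simulated ChIP-exo libraries.

    `border_offset` is the distance from the site center to each 5'-end
    border (forward upstream, reverse downstream); real exonuclease borders
    sit roughly one protein footprint from the crosslink, so the default
    half-width of 20 bases gives a 40-base protected region.
    """

    border_offset: int = 20
    border_jitter_sd: float = 3.0
    reads_per_site: float = 200.0
    background_rate: float = 0.01
    mock_fragment_min: int = 300
    mock_fragment_max: int = 500
    mock_fragments: int = 20_000
    depth_scale_per_replicate: tuple = (1.0, 1.0)

    def validate(self) -> None:
        if min(self.reads_per_site, self.background_rate, self.border_jitter_sd) < 0:
            raise ValueError("rates must be non-negative")
        if self.mock_fragment_min > self.mock_fragment_max:
            raise ValueError("mock_fragment_min must be <= mock_fragment_max")


@dataclass
class ExpressionModel:
    """Negative-binomial RNA-seq model, variance = mu + alpha * mu^2."""

    baseline_mean: float = 500.0
    dispersion: float = 0.05
    n_replicates: int = 3
    planted_lfc: float = 2.0

    def validate(self) -> None:
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be > 0")


# ---------------------------------------------------------------------------
# Reference genome and annotation
# ---------------------------------------------------------------------------

def generate_reference(spec: GenomeSpec, seed: int) -> tuple[str, pd.DataFrame]:
    """Random genome sequence plus a non-overlapping gene annotation.

    Gene lengths are drawn uniformly from [min_gene_len, max_gene_len]; the
    remaining slack is distributed over the n_genes + 1 intergenic gaps on
    top of `min_intergenic`, so the layout exactly tiles the genome.
    Consecutive genes join the previous gene's operon (sharing its strand)
    with probability `operon_prob`.
    """
    rng = child_rng(seed, "genome")
    p_gc = spec.gc / 2
    genome = "".join(
        rng.choice(np.array(list("ACGT")), size=spec.length,
                   p=[(1 - spec.gc) / 2, p_gc, p_gc, (1 - spec.gc) / 2])
    )
    if spec.n_genes == 0:
        return genome, pd.DataFrame(
            columns=["gene_id", "name", "strand", "start", "end", "operon_id", "cog"]
        )
    lengths = rng.integers(spec.min_gene_len, spec.max_gene_len + 1, size=spec.n_genes)
    required = int(lengths.sum()) + (spec.n_genes + 1) * spec.min_intergenic
    if required > spec.length:
        raise ValueError(
            f"unsatisfiable genome spec: {spec.n_genes} genes plus minimum intergenic "
            f"gaps need {required} bases but genome length is {spec.length}"
        )
    slack = spec.length - required
    extra = rng.multinomial(slack, np.full(spec.n_genes + 1, 1 / (spec.n_genes + 1)))
    rows = []
    pos = 0
    operon_counter = 0
    prev_strand = None
    for i in range(spec.n_genes):
        pos += spec.min_intergenic + int(extra[i])
        start, end = pos, pos + int(lengths[i])
        joins = i > 0 and rng.random() < spec.operon_prob
        if joins:
            strand = prev_strand
        else:
            strand = "+" if rng.random() < 0.5 else "-"
            operon_counter += 1
        rows.append(
            {
                "gene_id": f"g{i:04d}",
                "name": f"gene{i:04d}",
                "strand": strand,
                "start": start,
                "end": end,
                "operon_id": f"op{operon_counter:04d}",
                "cog": str(rng.choice(list(spec.cog_categories))),
            }
        )
        prev_strand = strand
        pos = end
    genes = pd.DataFrame(rows)
    return genome, genes


# ---------------------------------------------------------------------------
# Planted binding sites
# ---------------------------------------------------------------------------

def _realize_motif(motif: str, rng: np.random.Generator) -> str:
    try:
        return "".join(str(rng.choice(list(IUPAC[c]))) for c in motif.upper())
    except KeyError as exc:
        raise ValueError(f"non-IUPAC letter in motif: {exc}") from exc


def tss(gene: pd.Series) -> int:
    """Transcription-start coordinate: leftmost base for + genes, rightmost for -."""
    return int(gene.start) if gene.strand == "+" else int(gene.end) - 1


def plant_sites(
    genes: pd.DataFrame,
    genome: str,
    n_sites: int,
    regulatory_fraction: float,
    motif: str = "TTCNNNNNNGAA",
    seed: int = 0,
    upstream_max: int = 300,
    min_separation: int = 150,
    edge_margin: int = 30,
    unique_targets: bool = False,
) -> tuple[str, pd.DataFrame]:
    """Write motif instances into the genome at planted binding sites.

    round(n_sites * regulatory_fraction) sites are placed in intergenic DNA
    within `upstream_max` bases of a downstream gene start (the regulatory
    class); the rest inside gene bodies (intragenic), at least `edge_margin`
    bases from gene boundaries.  Site centers are kept `min_separation`
    bases apart.  The motif, given in IUPAC letters, is realized
    independently per site and overwrites the background sequence, centered
    on the site.
    """
    rng = child_rng(seed, "sites")
    motif = motif.upper()
    if n_sites == 0:
        return genome, _empty_sites()
    n_reg = int(round(n_sites * regulatory_fraction))
    n_intra = n_sites - n_reg
    half = len(motif) // 2

    # candidate windows
    reg_windows = []  # (lo, hi, gene row) for upstream intergenic placement
    gene_list = genes.sort_values("start").reset_index(drop=True)
    for i, g in gene_list.iterrows():
        if g.strand == "+":
            prev_end = int(gene_list.iloc[i - 1].end) if i > 0 else 0
            lo = max(prev_end + half, int(g.start) - upstream_max)
            hi = int(g.start) - half
        else:
            next_start = int(gene_list.iloc[i + 1].start) if i + 1 < len(gene_list) else len(genome)
            lo = int(g.end) + half
            hi = min(next_start - half, int(g.end) + upstream_max)
        if hi > lo:
            reg_windows.append((lo, hi, g))
    intra_windows = []
    for _, g in gene_list.iterrows():
        lo, hi = int(g.start) + edge_margin, int(g.end) - edge_margin
        if hi > lo:
            intra_windows.append((lo, hi, g))
    if not reg_windows and n_reg > 0:
        raise ValueError("motif longer than smallest regulatory placement window")
    if not intra_windows and n_intra > 0:
        raise ValueError("motif longer than smallest intragenic placement window")

    centers: list[int] = []
    used_genes: set[str] = set()
    rows = []

    def place(windows, n_wanted, location_class):
        placed = 0
        attempts = 0
        while placed < n_wanted:
            attempts += 1
            if attempts > 200 * n_wanted + 200:
                raise ValueError(
                    f"could not place {n_wanted} non-overlapping {location_class} sites"
                )
            lo, hi, g = windows[rng.integers(len(windows))]
            if unique_targets and g.gene_id in used_genes:
                continue
            c = int(rng.integers(lo, hi))
            if any(abs(c - c0) < min_separation for c0 in centers):
                continue
            used_genes.add(g.gene_id)
            centers.append(c)
            rows.append(
                {
                    "site_id": f"site{len(rows):03d}",
                    "tf_name": "TF1",
                    "center": c,
                    "motif_instance": _realize_motif(motif, rng),
                    "location_class_truth": location_class,
                    "target_gene_truth": g.gene_id,
                    "cooccupancy_truth": "others",
                    "regulatory_mode_truth": "none",
                }
            )
            placed += 1

    place(reg_windows, n_reg, "regulatory")
    place(intra_windows, n_intra, "intragenic")

    seq = list(genome)
    for row in rows:
        start = row["center"] - half
        seq[start:start + len(motif)] = row["motif_instance"]
    sites = pd.DataFrame(rows).sort_values("center").reset_index(drop=True)
    return "".join(seq), sites


def _empty_sites() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "site_id", "tf_name", "center", "motif_instance",
            "location_class_truth", "target_gene_truth",
            "cooccupancy_truth", "regulatory_mode_truth",
        ]
    )


# ---------------------------------------------------------------------------
# ChIP-exo coverage
# ---------------------------------------------------------------------------

def simulate_exo_coverage(
    sites: pd.DataFrame,
    model: ReadModel,
    genome_length: int,
    n_replicates: int = 2,
    seed: int = 0,
) -> dict[str, dict[str, StrandCoverage]]:
    """Strand-specific 5'-end tracks for IP replicates plus one mock sample.

    Each planted site contributes Poisson(reads_per_site) forward-strand 5'
    ends jittered around center - border_offset and the same around
    center + border_offset on the reverse strand; background 5' ends are
    uniform per strand.  The mock sample records both 5' ends of uniformly
    placed sheared fragments of 300-500 bp, independent of the sites.
    """
    model.validate()
    rng = child_rng(seed, "exo")
    out: dict[str, dict[str, StrandCoverage]] = {}
    scales = list(model.depth_scale_per_replicate) + [1.0] * n_replicates
    for r in range(n_replicates):
        sample = f"ip{r + 1}"
        scale = scales[r]
        tracks = {}
        for strand, sign in (("+", -1), ("-", +1)):
            values = rng.poisson(model.background_rate * scale, genome_length).astype(float)
            for center in sites["center"].to_numpy(dtype=int) if len(sites) else []:
                border = center + sign * model.border_offset
                n = rng.poisson(model.reads_per_site * scale)
                pos = np.rint(border + rng.normal(0, model.border_jitter_sd, n)).astype(int)
                pos = np.clip(pos, 0, genome_length - 1)
                np.add.at(values, pos, 1.0)
            tracks[strand] = StrandCoverage(sample_id=sample, strand=strand, values=values)
        out[sample] = tracks

    mock_rng = child_rng(seed, "mock")
    fwd = np.zeros(genome_length, dtype=float)
    rev = np.zeros(genome_length, dtype=float)
    n_frag = mock_rng.poisson(model.mock_fragments)
    frag_len = mock_rng.integers(model.mock_fragment_min, model.mock_fragment_max + 1, n_frag)
    starts = mock_rng.integers(0, np.maximum(1, genome_length - frag_len))
    np.add.at(fwd, starts, 1.0)
    np.add.at(rev, np.minimum(starts + frag_len - 1, genome_length - 1), 1.0)
    out["mock"] = {
        "+": StrandCoverage(sample_id="mock", strand="+", values=fwd),
        "-": StrandCoverage(sample_id="mock", strand="-", values=rev),
    }
    return out


# ---------------------------------------------------------------------------
# RNAP / RpoD occupancy
# ---------------------------------------------------------------------------

def simulate_occupancy(
    genes: pd.DataFrame,
    fractions: dict[str, float],
    promoter_upstream: int = 300,
    promoter_downstream: int = 50,
    genome_length: int | None = None,
    seed: int = 0,
) -> tuple[list[tuple[int, int]], list[tuple[int, int]], pd.DataFrame]:
    """Assign each operon-lead promoter a co-occupancy class and emit peaks.

    `fractions` gives probabilities for classes rnap_rpod / rnap_only /
    none (must sum to 1).  A promoter in class rnap_rpod receives
    overlapping RNAP and RpoD peaks covering its promoter interval;
    rnap_only receives the RNAP peak only; none receives neither, so an
    RpoD peak never exists without RNAP at the same promoter.
    """
    total = sum(fractions.get(k, 0.0) for k in ("rnap_rpod", "rnap_only", "none"))
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"occupancy fractions must sum to 1, got {total}")
    rng = child_rng(seed, "occupancy")
    classes = ["rnap_rpod", "rnap_only", "none"]
    probs = [fractions.get(k, 0.0) for k in classes]
    leads = genes.drop_duplicates("operon_id", keep="first") if "operon_id" in genes else genes
    # a "-"-strand operon's lead promoter belongs to its rightmost member
    if "operon_id" in genes.columns and len(genes):
        lead_rows = []
        for _, grp in genes.groupby("operon_id", sort=False):
            grp = grp.sort_values("start")
            lead_rows.append(grp.iloc[0] if grp.iloc[0].strand == "+" else grp.iloc[-1])
        leads = pd.DataFrame(lead_rows)
    rnap, rpod, labels = [], [], []
    for _, g in leads.iterrows():
        label = classes[rng.choice(3, p=probs)]
        s = tss(g)
        if g.strand == "+":
            lo, hi = max(0, s - promoter_upstream), s + promoter_downstream
        else:
            lo, hi = max(0, s - promoter_downstream + 1), s + promoter_upstream + 1
        if genome_length is not None:
            hi = min(hi, genome_length)
        if label in ("rnap_rpod", "rnap_only"):
            rnap.append((lo, hi))
        if label == "rnap_rpod":
            rpod.append((lo, hi))
        labels.append({"gene_id": g.gene_id, "operon_id": g.get("operon_id", ""),
                       "cooccupancy_truth": label})
    return sorted(rnap), sorted(rpod), pd.DataFrame(labels)


# ---------------------------------------------------------------------------
# RNA-seq counts
# ---------------------------------------------------------------------------

def simulate_rnaseq(
    genes: pd.DataFrame,
    direct_targets: dict[str, str],
    model: ExpressionModel,
    seed: int = 0,
) -> pd.DataFrame:
    """Gene x sample count matrix for wild type and knockout.

    `direct_targets` maps gene_id -> direction of change in the knockout
    ("up" or "down"); non-target genes keep the same mean in both
    conditions.  Counts are negative binomial with variance mu + alpha*mu^2
    (Poisson when dispersion is 0).
    """
    model.validate()
    unknown = set(direct_targets) - set(genes["gene_id"])
    if unknown:
        raise ValueError(f"unknown gene ids in direct_targets: {sorted(unknown)[:5]}")
    rng = child_rng(seed, "rnaseq")
    gene_ids = genes["gene_id"].tolist()
    mu_wt = np.full(len(gene_ids), model.baseline_mean)
    shift = np.zeros(len(gene_ids))
    for i, gid in enumerate(gene_ids):
        if gid in direct_targets:
            d = direct_targets[gid]
            if d not in ("up", "down"):
                raise ValueError(f"direction must be up/down, got {d!r}")
            shift[i] = model.planted_lfc if d == "up" else -model.planted_lfc
    mu_ko = mu_wt * np.power(2.0, shift)

    def draw(mu: np.ndarray) -> np.ndarray:
        if model.dispersion == 0:
            return rng.poisson(mu)
        size = 1.0 / model.dispersion
        return rng.negative_binomial(size, size / (size + mu))

    data = {}
    for r in range(model.n_replicates):
        data[f"WT_{r + 1}"] = draw(mu_wt)
    for r in range(model.n_replicates):
        data[f"KO_{r + 1}"] = draw(mu_ko)
    return pd.DataFrame(data, index=pd.Index(gene_ids, name="gene_id"))


def _cooccupancy_truth(
    sites: pd.DataFrame,
    genes: pd.DataFrame,
    rnap: list[tuple[int, int]],
    rpod: list[tuple[int, int]],
    upstream_max: int,
    promoter_downstream: int,
    genome_length: int,
) -> list[str]:
    """Ground-truth co-occupancy class per planted site.

    A regulatory site's class is the best machinery occupancy over its
    qualifying target promoters — the nearest downstream gene start on
    each strand within `upstream_max` (a divergent site qualifies two) —
    where occupancy is a plain interval-overlap scan of the promoter
    window against the emitted RNAP/RpoD peak lists.  Intragenic sites
    are "others" by definition.
    """
    rank = {"rnap_rpod": 2, "rnap_only": 1, "none": 0}
    by_strand = {}
    for strand in "+-":
        sub = genes[genes["strand"] == strand]
        starts = sub.apply(tss, axis=1).to_numpy() if len(sub) else np.array([], dtype=int)
        order = starts.argsort()
        by_strand[strand] = (starts[order], sub.iloc[order]["strand"].to_numpy())

    def hits(lo: int, hi: int, intervals) -> bool:
        return any(min(e, hi) > max(s, lo) for s, e in intervals)

    def promoter_label(s: int, strand: str) -> str:
        if strand == "+":
            lo, hi = max(0, s - upstream_max), min(genome_length, s + promoter_downstream)
        else:
            lo, hi = max(0, s - promoter_downstream + 1), min(genome_length, s + upstream_max + 1)
        has_rnap, has_rpod = hits(lo, hi, rnap), hits(lo, hi, rpod)
        return "rnap_rpod" if (has_rnap and has_rpod) else ("rnap_only" if has_rnap else "none")

    out = []
    for _, s in sites.iterrows():
        if s.location_class_truth != "regulatory":
            out.append("others")
            continue
        c = int(s.center)
        best = "none"
        starts, _ = by_strand["+"]
        i = int(np.searchsorted(starts, c, side="right"))
        if i < len(starts) and 0 < starts[i] - c <= upstream_max:
            lab = promoter_label(int(starts[i]), "+")
            best = lab if rank[lab] > rank[best] else best
        starts, _ = by_strand["-"]
        i = int(np.searchsorted(starts, c, side="left")) - 1
        if i >= 0 and 0 < c - starts[i] <= upstream_max:
            lab = promoter_label(int(starts[i]), "-")
            best = lab if rank[lab] > rank[best] else best
        out.append(best if best != "none" else "others")
    return out


# ---------------------------------------------------------------------------
# Full scenario
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    genome: str
    genes: pd.DataFrame
    sites: pd.DataFrame
    tracks: dict[str, dict[str, StrandCoverage]]
    rnap: list[tuple[int, int]]
    rpod: list[tuple[int, int]]
    occupancy_truth: pd.DataFrame
    counts: pd.DataFrame
    direct_targets: dict[str, str]
    seed: int = 0


def simulate_dataset(
    genome_spec: GenomeSpec | None = None,
    read_model: ReadModel | None = None,
    expression_model: ExpressionModel | None = None,
    n_sites: int = 50,
    regulatory_fraction: float = 0.6,
    motif: str = "TTCNNNNNNGAA",
    n_replicates: int = 2,
    occupancy_fractions: dict[str, float] | None = None,
    n_direct: int = 20,
    repressed_fraction: float = 0.8,
    upstream_max: int = 300,
    promoter_downstream: int = 50,
    seed: int = 0,
) -> SimulatedDataset:
    """One seeded end-to-end study: genome, sites, tracks, occupancy, counts.

    Defaults emulate a local regulator with 50 binding sites, 60% of them
    regulatory, of whose target genes 20 respond to the knockout (16 up =
    repressed by the TF, 4 down = activated), with planted |log2FC| = 2.
    """
    genome_spec = genome_spec or GenomeSpec()
    read_model = read_model or ReadModel()
    expression_model = expression_model or ExpressionModel()
    occupancy_fractions = occupancy_fractions or {"rnap_rpod": 0.5, "rnap_only": 0.25, "none": 0.25}

    genome, genes = generate_reference(genome_spec, seed)
    genome, sites = plant_sites(
        genes, genome, n_sites, regulatory_fraction, motif=motif, seed=seed,
        upstream_max=upstream_max, unique_targets=True,
    )
    tracks = simulate_exo_coverage(sites, read_model, len(genome), n_replicates, seed)
    rnap, rpod, occ_truth = simulate_occupancy(
        genes, occupancy_fractions, upstream_max, promoter_downstream,
        genome_length=len(genome), seed=seed,
    )
    sites = sites.assign(
        cooccupancy_truth=_cooccupancy_truth(
            sites, genes, rnap, rpod, upstream_max, promoter_downstream, len(genome)
        )
    )

    rng = child_rng(seed, "scenario")
    bound = sorted(sites["target_gene_truth"].unique())
    n_direct_eff = min(n_direct, len(bound))
    chosen = list(rng.choice(bound, size=n_direct_eff, replace=False))
    n_up = int(round(repressed_fraction * n_direct_eff))
    direct = {g: ("up" if i < n_up else "down") for i, g in enumerate(chosen)}
    modes = ["none"] * len(sites)
    for i, s in sites.iterrows():
        if s.target_gene_truth in direct:
            modes[i] = "repressor" if direct[s.target_gene_truth] == "up" else "activator"
    sites = sites.assign(regulatory_mode_truth=modes)

    counts = simulate_rnaseq(genes, direct, expression_model, seed)
    return SimulatedDataset(
        genome=genome, genes=genes, sites=sites, tracks=tracks,
        rnap=rnap, rpod=rpod, occupancy_truth=occ_truth,
        counts=counts, direct_targets=direct, seed=seed,
    )
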