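"""In-silico plasma RNA study generator with recorded ground truth.

The generator emulates the statistical structure the analysis assumes: a
small two-group study (10 case / 8 control samples) with negative-binomial
counts for circRNA, miRNA and mRNA; a global multiplicative down-shift of
circRNA abundance in cases; planted differential expression in all three
RNA classes; circRNAs exclusively expressed in one group; two caller
call-sets that are independently thinned views of the true circRNA set; and
miRNA/target sequences carrying planted complementary response elements at
recorded positions. Every planted fact is recorded in a ground-truth object
so downstream stages are testable without external data.

Counts are drawn from a single RNG stream ordered by (class, feature,
sample), so a given seed yields a byte-identical bundle.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_formats
from .io_formats import BSJCall, GeneModel
from .quantify import CASE, CONTROL, ExpressionMatrix

_RNA_COMPLEMENT = {"A": "U", "U": "A", "C": "G", "G": "C"}
CLASSES = ("circ", "mirna", "mrna")


@dataclass
class SimulationConfig:
    """Study-design parameters; defaults are the emulated study conditions."""

    n_case: int = 10
    n_control: int = 8
    n_circ: int = 300
    n_mirna: int = 150
    n_mrna: int = 1000
    # NB mean / dispersion per RNA class (variance = mu + alpha * mu^2)
    nb_mean: dict = field(default_factory=lambda: {"circ": 20.0, "mirna": 200.0, "mrna": 100.0})
    nb_dispersion: dict = field(default_factory=lambda: {"circ": 0.3, "mirna": 0.2, "mrna": 0.2})
    case_circ_downshift: float = 0.5  # global multiplicative factor on case circRNA means
    frac_de: dict = field(default_factory=lambda: {"circ": 0.1, "mirna": 0.1, "mrna": 0.1})
    de_fold_change: float = 4.0
    # fraction of DE features that are up-regulated in cases, per class
    frac_up: dict = field(default_factory=lambda: {"circ": 0.05, "mirna": 0.6, "mrna": 0.8})
    n_exclusive_case: int = 10
    n_exclusive_control: int = 40
    mre_plant_rate: float = 0.05
    caller_dropout: float = 0.15  # per-caller fraction of true circRNAs missed
    corr_coupling_strength: float = 0.4  # case-group shared-factor scale, log space
    mapped_total_mean: float = 1e6
    mapped_total_sigma: float = 0.3
    mirna_length: int = 22
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_case, self.n_control, self.n_circ, self.n_mirna, self.n_mrna) <= 0:
            raise ValueError("all counts must be positive")
        if not 0 < self.case_circ_downshift <= 1:
            raise ValueError("case_circ_downshift must be in (0, 1]")
        if any(v <= 0 for v in self.nb_dispersion.values()):
            raise ValueError("dispersions must be > 0")
        if self.n_exclusive_case + self.n_exclusive_control >= self.n_circ:
            raise ValueError("more exclusive circRNAs than available features")


@dataclass
class GroundTruth:
    """Everything that was planted, for recovery checks."""

    true_de: dict  # class -> {feature_id: "Up"/"Down"} (case vs control)
    exclusive_case: list
    exclusive_control: list
    planted_mres: list  # (mirna_id, target_id, 1-based position)
    consensus_circ_ids: list  # true circRNAs observable by both callers
    caller_a_circ_ids: list
    caller_b_circ_ids: list
    coupled_circ: list
    coupled_mrna: list
    annotation_classes: dict  # circ_id -> class
    enriched_term: str


@dataclass
class StudyBundle:
    config: SimulationConfig
    groups: pd.Series
    calls_a: list  # find_circ BSJCalls, all samples
    calls_b: list  # circexplorer2 BSJCalls
    circ_counts: ExpressionMatrix
    mirna_counts: ExpressionMatrix
    mrna_counts: ExpressionMatrix
    mirna_seqs: dict
    target_seqs: dict  # circRNA and mRNA sequences, keyed by feature id
    gene_models: list
    gene_sets: dict
    truth: GroundTruth


def reverse_complement_rna(seq: str) -> str:
    return "".join(_RNA_COMPLEMENT[b] for b in reversed(seq.upper().replace("T", "U")))


def plant_mre(mirna_seq: str, target_seq: str, position: int, extent: int | None = None) -> str:
    """Insert the reverse complement of the miRNA 5' region into the target.

    ``position`` is 1-based; ``extent`` is how many miRNA 5' bases the site
    complements (default: the full miRNA). Returns the modified target.
    """
    mirna = mirna_seq.upper().replace("T", "U")
    if extent is None:
        extent = len(mirna)
    site = reverse_complement_rna(mirna[:extent])
    if position < 1 or position - 1 + len(site) > len(target_seq):
        raise ValueError(
            f"site of length {len(site)} at position {position} exceeds target "
            f"length {len(target_seq)}"
        )
    i = position - 1
    return target_seq[:i] + site + target_seq[i + len(site):]


def _random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=length))


def _make_gene_models(config: SimulationConfig, rng: np.random.Generator):
    """Coding and lncRNA gene models plus circRNA placements on them."""
    n_coding = max(config.n_circ // 3, 1)
    n_lnc = max(config.n_circ // 50, 2)
    exon_len, intron_len, n_exons = 150, 350, 8
    gene_span = n_exons * exon_len + (n_exons - 1) * intron_len
    genes: list[GeneModel] = []
    for g in range(n_coding + n_lnc):
        chrom = f"chr{(g % 22) + 1}"
        offset = 100_000 + (g // 22) * 100_000
        coding = g < n_coding
        ne = n_exons if coding else 2
        exons = [(offset + k * (exon_len + intron_len),
                  offset + k * (exon_len + intron_len) + exon_len) for k in range(ne)]
        genes.append(GeneModel(
            gene_id=f"GENE{g:04d}" if coding else f"LNC{g - n_coding:03d}",
            gene_type="protein_coding" if coding else "lncRNA",
            transcript_id=f"TX{g:04d}",
            chrom=chrom,
            strand="+" if g % 2 == 0 else "-",
            exons=exons,
        ))
    del gene_span

    # placements: ~1% intergenic, ~2% lncRNA, ~2% sense-intronic, rest coding
    placements = []
    seen: set[str] = set()
    for i in range(config.n_circ):
        u = rng.random()
        for _ in range(200):
            if u < 0.01:
                chrom = f"chr{int(rng.integers(1, 23))}"
                start = int(rng.integers(10_000_000, 20_000_000))
                end = start + int(rng.integers(200, 2000))
                cls, strand = "intergenic", "+"
            elif u < 0.03:
                g = genes[n_coding + int(rng.integers(0, n_lnc))]
                start = g.exons[0][0] + 10
                end = start + int(rng.integers(200, 600))
                chrom, cls, strand = g.chrom, "lncRNA", g.strand
            elif u < 0.05:
                g = genes[int(rng.integers(0, n_coding))]
                istart, iend = g.introns[0]
                start = istart + int(rng.integers(10, 100))
                end = start + int(rng.integers(100, iend - start - 5))
                chrom, cls, strand = g.chrom, "sense_intronic", g.strand
            else:
                g = genes[int(rng.integers(0, n_coding))]
                a = int(rng.integers(0, len(g.exons) - 1))
                b = int(rng.integers(a + 1, len(g.exons)))
                start, end = g.exons[a][0], g.exons[b][1]
                chrom, cls, strand = g.chrom, "protein_coding", g.strand
            circ_id = f"{chrom}_{start}_{end}"
            if circ_id not in seen:
                seen.add(circ_id)
                placements.append((circ_id, chrom, start, end, strand, cls))
                break
        else:
            raise RuntimeError("could not place a unique circRNA")
    return genes, placements


def _draw_counts(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """Row-ordered NB draws; zero mean gives a structural zero."""
    out = np.zeros(mu.shape, dtype=int)
    r = 1.0 / alpha
    for i in range(mu.shape[0]):  # feature-major order for RNG stability
        row = mu[i]
        pos = row > 0
        if pos.any():
            out[i, pos] = rng.negative_binomial(r, r / (r + row[pos]))
    return out


def simulate_study(config: SimulationConfig | None = None) -> StudyBundle:
    """Generate a complete in-silico study bundle (see module docstring)."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)

    case_ids = [f"P{i + 1:02d}" for i in range(config.n_case)]
    control_ids = [f"C{i + 1:02d}" for i in range(config.n_control)]
    samples = case_ids + control_ids
    groups = pd.Series([CASE] * config.n_case + [CONTROL] * config.n_control,
                       index=samples, name="group")
    case_mask = np.array([g == CASE for g in groups])

    genes, placements = _make_gene_models(config, rng)
    circ_ids = [p[0] for p in placements]
    mirna_ids = [f"mir-{i + 1:03d}" for i in range(config.n_mirna)]
    mrna_ids = [f"MRNA{i + 1:04d}" for i in range(config.n_mrna)]
    ids = {"circ": circ_ids, "mirna": mirna_ids, "mrna": mrna_ids}

    # planted feature roles -----------------------------------------------
    circ_perm = rng.permutation(config.n_circ)
    excl_case = sorted(circ_ids[i] for i in circ_perm[: config.n_exclusive_case])
    excl_control = sorted(
        circ_ids[i]
        for i in circ_perm[config.n_exclusive_case:
                           config.n_exclusive_case + config.n_exclusive_control]
    )
    exclusive = set(excl_case) | set(excl_control)

    true_de: dict[str, dict[str, str]] = {}
    for cls in CLASSES:
        pool = [f for f in ids[cls] if f not in exclusive]
        n_de = int(round(config.frac_de[cls] * len(ids[cls])))
        chosen = list(rng.choice(pool, size=min(n_de, len(pool)), replace=False))
        ups = rng.random(len(chosen)) < config.frac_up[cls]
        true_de[cls] = {f: ("Up" if u else "Down") for f, u in zip(chosen, ups)}

    # planted response elements between DE miRNAs and DE circ/mRNAs --------
    de_mirnas = sorted(true_de["mirna"])
    planted_pairs = []
    for cls in ("circ", "mrna"):
        for t in sorted(true_de[cls]):
            for m in de_mirnas:
                if rng.random() < config.mre_plant_rate:
                    planted_pairs.append((m, t))
    coupled_circ = sorted({t for m, t in planted_pairs
                           if t in true_de["circ"] and true_de["circ"][t] != true_de["mirna"][m]})
    coupled_mrna = sorted({t for m, t in planted_pairs
                           if t in true_de["mrna"] and true_de["mrna"][t] != true_de["mirna"][m]})

    # case-group shared latent factor (parallel-correlation structure)
    latent = rng.normal(size=config.n_case)
    coupling = np.exp(config.corr_coupling_strength * latent)

    # count matrices --------------------------------------------------------
    matrices: dict[str, pd.DataFrame] = {}
    for cls in CLASSES:
        feats = ids[cls]
        base = rng.lognormal(np.log(config.nb_mean[cls]), 0.5, size=len(feats))
        mu = np.tile(base[:, None], (1, len(samples)))
        if cls == "circ":
            mu[:, case_mask] *= config.case_circ_downshift
        for i, f in enumerate(feats):
            status = true_de[cls].get(f)
            if status == "Up":
                mu[i, case_mask] *= config.de_fold_change
            elif status == "Down":
                mu[i, case_mask] /= config.de_fold_change
            if cls == "circ" and f in exclusive:
                boosted = max(base[i], 15.0)
                if f in set(excl_case):
                    mu[i, :] = np.where(case_mask, boosted, 0.0)
                else:
                    mu[i, :] = np.where(case_mask, 0.0, boosted)
        coupled = set(coupled_circ if cls == "circ" else (coupled_mrna if cls == "mrna" else []))
        if coupled:
            rows = [i for i, f in enumerate(feats) if f in coupled]
            mu[np.ix_(rows, np.flatnonzero(case_mask))] *= coupling
        counts = _draw_counts(rng, mu, config.nb_dispersion[cls])
        matrices[cls] = pd.DataFrame(counts, index=feats, columns=samples)

    mapped_totals = pd.Series(
        rng.lognormal(np.log(config.mapped_total_mean), config.mapped_total_sigma,
                      size=len(samples)),
        index=samples, name="mapped_total",
    ).round().astype(float)

    # caller views -----------------------------------------------------------
    kept_a = rng.random(config.n_circ) >= config.caller_dropout
    kept_b = rng.random(config.n_circ) >= config.caller_dropout
    observed = (matrices["circ"].to_numpy() > 0)
    calls_a, calls_b = [], []
    ids_a, ids_b, ids_both = [], [], []
    for i, (circ_id, chrom, start, end, strand, _cls) in enumerate(placements):
        if not observed[i].any():
            continue
        if kept_a[i]:
            ids_a.append(circ_id)
        if kept_b[i]:
            ids_b.append(circ_id)
        if kept_a[i] and kept_b[i]:
            ids_both.append(circ_id)
        for j, smp in enumerate(samples):
            reads = int(matrices["circ"].iat[i, j])
            if reads <= 0:
                continue
            if kept_a[i]:
                calls_a.append(BSJCall(chrom, start, end, strand, reads, "find_circ", smp))
            if kept_b[i]:
                calls_b.append(BSJCall(chrom, start, end, strand, reads, "circexplorer2", smp))

    # sequences with planted complementary sites -----------------------------
    mirna_seqs = {m: _random_rna(rng, config.mirna_length) for m in mirna_ids}
    target_seqs: dict[str, str] = {}
    for c in circ_ids:
        target_seqs[c] = _random_rna(rng, int(rng.integers(300, 1200)))
    for m in mrna_ids:
        target_seqs[m] = _random_rna(rng, int(rng.integers(500, 1500)))

    planted_mres: list[tuple[str, str, int]] = []
    occupied: dict[str, list[tuple[int, int]]] = {}
    site_len = config.mirna_length
    for m, t in planted_pairs:
        seq = target_seqs[t]
        for _ in range(30):
            pos = int(rng.integers(1, len(seq) - site_len + 2))
            span = (pos, pos + site_len - 1)
            if all(span[1] < s or span[0] > e for s, e in occupied.get(t, [])):
                target_seqs[t] = plant_mre(mirna_seqs[m], target_seqs[t], pos)
                occupied.setdefault(t, []).append(span)
                planted_mres.append((m, t, pos))
                break

    # gene-set annotation with one planted enriched term ---------------------
    gene_sets: dict[str, set[str]] = {}
    de_mrnas = sorted(true_de["mrna"])
    n_enriched = min(20, len(de_mrnas))
    planted_term = "T01"
    gene_sets[planted_term] = set(
        rng.choice(de_mrnas, size=n_enriched, replace=False)
    ) | set(rng.choice(mrna_ids, size=10, replace=False))
    for k in range(2, 21):
        gene_sets[f"T{k:02d}"] = set(rng.choice(mrna_ids, size=30, replace=False))

    def em(cls: str) -> ExpressionMatrix:
        return ExpressionMatrix(matrices[cls], groups, mapped_totals, unit="raw_count")

    truth = GroundTruth(
        true_de=true_de,
        exclusive_case=excl_case,
        exclusive_control=excl_control,
        planted_mres=planted_mres,
        consensus_circ_ids=sorted(ids_both),
        caller_a_circ_ids=sorted(ids_a),
        caller_b_circ_ids=sorted(ids_b),
        coupled_circ=coupled_circ,
        coupled_mrna=coupled_mrna,
        annotation_classes={p[0]: p[5] for p in placements},
        enriched_term=planted_term,
    )
    return StudyBundle(
        config=config, groups=groups, calls_a=calls_a, calls_b=calls_b,
        circ_counts=em("circ"), mirna_counts=em("mirna"), mrna_counts=em("mrna"),
        mirna_seqs=mirna_seqs, target_seqs=target_seqs,
        gene_models=genes, gene_sets=gene_sets, truth=truth,
    )


def write_bundle(bundle: StudyBundle, outdir: str | Path) -> dict[str, str]:
    """Serialize every bundle component through io_formats; returns the paths."""
    outdir = Path(outdir)
    for caller in ("find_circ", "circexplorer2"):
        (outdir / "calls" / caller).mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    by_sample: dict[tuple[str, str], list[BSJCall]] = {}
    for call in bundle.calls_a + bundle.calls_b:
        by_sample.setdefault((call.caller, call.sample_id), []).append(call)
    for smp in bundle.groups.index:
        for caller in ("find_circ", "circexplorer2"):
            p = outdir / "calls" / caller / f"{smp}.bed"
            io_formats.write_bsj_calls(
                sorted(by_sample.get((caller, smp), []),
                       key=lambda c: (c.chrom, c.start, c.end)),
                p, caller)
            paths[f"calls/{caller}/{smp}"] = str(p)

    for name, em in (("circ_counts", bundle.circ_counts),
                     ("mirna_counts", bundle.mirna_counts),
                     ("mrna_counts", bundle.mrna_counts)):
        p = outdir / f"{name}.tsv"
        io_formats.write_count_matrix(em.values, p)
        paths[name] = str(p)
    io_formats.write_groups(bundle.groups, outdir / "groups.tsv")
    io_formats.write_mapped_totals(bundle.circ_counts.mapped_totals,
                                   outdir / "mapped_totals.tsv")
    io_formats.write_fasta(bundle.mirna_seqs, outdir / "mirna.fa")
    io_formats.write_fasta(bundle.target_seqs, outdir / "targets.fa")
    io_formats.write_gene_models(bundle.gene_models, outdir / "gene_models.tsv")
    io_formats.write_gene_sets(bundle.gene_sets, outdir / "gene_sets.tsv")
    truth = asdict(bundle.truth)
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    for name in ("groups", "mapped_totals", "mirna", "targets",
                 "gene_models", "gene_sets", "truth"):
        suffix = {"mirna": "mirna.fa", "targets": "targets.fa",
                  "truth": "truth.json"}.get(name, f"{name}.tsv")
        paths[name] = str(outdir / suffix)
    return paths


def bundle_digest(bundle: StudyBundle) -> str:
    """Deterministic content hash of a bundle (reproducibility checks)."""
    h = hashlib.sha256()
    for em in (bundle.circ_counts, bundle.mirna_counts, bundle.mrna_counts):
        h.update(em.values.to_csv().encode())
    h.update(bundle.groups.to_csv().encode())
    h.update(bundle.circ_counts.mapped_totals.to_csv().encode())
    for call in bundle.calls_a + bundle.calls_b:
        h.update(repr(call).encode())
    for d in (bundle.mirna_seqs, bundle.target_seqs):
        for k in sorted(d):
            h.update(f"{k}:{d[k]}".encode())
    h.update(json.dumps(asdict(bundle.truth), sort_keys=True).encode())
    return h.hexdigest()
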