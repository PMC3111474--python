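"""Readers and writers for the pipeline's file formats.

Sequences are FASTA with ids ``species|gene``; the tree is Newick with
branch lengths; the motif is a 4-column tab-delimited count/probability
matrix or MEME-minimal; expression matrices, cluster labels, ortholog maps,
results and null distributions are tab-delimited text.  Tabular outputs
carry a single header line starting with ``#``; coordinates are 0-based
half-open.  Model parameters and run configuration round-trip through YAML.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO, motifs as bio_motifs

from .ctmc import RateParams
from .expression import ExpressionParams
from .model import GroupPosterior, ModelParams, OrthologGroup, classify_conservation
from .motif import MotifScanSummary, PSSM, SequenceModelParams, UNIFORM_BG, build_pssm
from .phylo import Phylogeny

__all__ = [
    "GroupInput",
    "InputBundle",
    "RunConfig",
    "read_tree",
    "read_fasta",
    "read_promoters",
    "read_pssm",
    "write_pssm",
    "read_expression",
    "read_labels",
    "write_labels",
    "read_ortholog_map",
    "read_inputs",
    "write_results",
    "read_results",
    "write_scans",
    "write_truth",
    "read_truth",
    "params_to_dict",
    "params_from_dict",
    "save_params",
    "load_params",
]

log = logging.getLogger("tnevo")


# ----------------------------------------------------------------------
# basic formats
# ----------------------------------------------------------------------


def read_tree(path) -> Phylogeny:
    return Phylogeny.from_newick_file(path)


def read_fasta(path) -> dict[str, str]:
    """FASTA file -> id -> uppercase sequence; duplicate ids are an error."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        out[rec.id] = str(rec.seq).upper()
    if not out:
        raise ValueError(f"{path}: no FASTA records")
    return out


def read_promoters(path) -> dict[str, dict[str, str]]:
    """FASTA with ``species|gene`` ids -> species -> gene -> sequence."""
    out: dict[str, dict[str, str]] = {}
    for seq_id, seq in read_fasta(path).items():
        if "|" not in seq_id:
            raise ValueError(f"{path}: id {seq_id!r} is not of the form species|gene")
        sp, gene = seq_id.split("|", 1)
        out.setdefault(sp, {})
        if gene in out[sp]:
            raise ValueError(f"{path}: duplicate gene id {gene!r} for species {sp!r}")
        out[sp][gene] = seq
    return out


def write_fasta(path, records: Mapping[str, str]) -> None:
    with open(path, "w") as fh:
        for seq_id, seq in records.items():
            fh.write(f">{seq_id}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def read_pssm(
    path,
    pseudocount: float = 0.0,
    background: Sequence[float] = UNIFORM_BG,
) -> PSSM:
    """Motif matrix from 4-column tab-delimited counts/probabilities or
    MEME-minimal format (auto-detected)."""
    path = Path(path)
    text = path.read_text()
    if "MEME version" in text:
        with open(path) as fh:
            records = bio_motifs.parse(fh, "minimal")
        if not records:
            raise ValueError(f"{path}: no motifs in MEME file")
        motif = records[0]
        counts = np.array([[motif.counts[b][i] for b in "ACGT"] for i in range(motif.length)])
        return build_pssm(counts, pseudocount=pseudocount, background=background, name=motif.name or path.stem)
    rows = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.replace(",", "\t").split()
        if len(fields) != 4:
            raise ValueError(f"{path}:{lineno}: expected 4 columns (A C G T), got {len(fields)}")
        try:
            rows.append([float(x) for x in fields])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric entry") from exc
    if not rows:
        raise ValueError(f"{path}: empty motif matrix")
    return build_pssm(np.array(rows), pseudocount=pseudocount, background=background, name=path.stem)


def write_pssm(path, pssm: PSSM) -> None:
    with open(path, "w") as fh:
        fh.write("# A\tC\tG\tT\n")
        for row in pssm.probs:
            fh.write("\t".join(f"{x:.6g}" for x in row) + "\n")


def read_expression(path) -> pd.DataFrame:
    """Expression TSV: rows = genes (first column), columns = conditions; header required."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment=None)
    if df.shape[1] < 1:
        raise ValueError(f"{path}: no condition columns")
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].tolist()[:3]
        raise ValueError(f"{path}: duplicate gene ids {dupes}")
    return df


def read_labels(path) -> dict[str, dict[str, int]]:
    """Cluster-label TSV (species, gene, label) -> species -> gene -> label."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=["species", "gene", "label"])
    out: dict[str, dict[str, int]] = {}
    for _, row in df.iterrows():
        sp, gene = str(row["species"]), str(row["gene"])
        out.setdefault(sp, {})
        if gene in out[sp]:
            raise ValueError(f"{path}: duplicate label for {sp}|{gene}")
        out[sp][gene] = int(row["label"])
    return out


def write_labels(path, labels: Mapping[str, Mapping[str, int]]) -> None:
    with open(path, "w") as fh:
        fh.write("# species\tgene\tlabel\n")
        for sp in sorted(labels):
            for gene in sorted(labels[sp]):
                fh.write(f"{sp}\t{gene}\t{labels[sp][gene]}\n")


def read_ortholog_map(path) -> pd.DataFrame:
    """Ortholog TSV: first column group id, one column per species (header
    line starting with '#'), one gene id per species."""
    with open(path) as fh:
        header = fh.readline()
    if not header.startswith("#"):
        raise ValueError(f"{path}: expected a '#'-prefixed header line")
    cols = header.lstrip("#").strip().split("\t")
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=cols, index_col=0, dtype=str)
    if df.index.duplicated().any():
        raise ValueError(f"{path}: duplicate group ids")
    return df


def write_ortholog_map(path, ortholog_map: pd.DataFrame) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join([ortholog_map.index.name or "group"] + list(ortholog_map.columns)) + "\n")
        ortholog_map.to_csv(fh, sep="\t", header=False)


# ----------------------------------------------------------------------
# assembled inputs
# ----------------------------------------------------------------------


@dataclass(frozen=True)
class GroupInput:
    """Raw per-group inputs before scanning."""

    group_id: str
    genes: dict[str, str]
    sequences: dict[str, str]
    labels: dict[str, int]


@dataclass(frozen=True)
class InputBundle:
    tree: Phylogeny
    pssm: PSSM
    records: list[GroupInput]
    n_dropped: int


@dataclass
class RunConfig:
    """Paths and model settings for one run; round-trips through YAML."""

    tree: str = ""
    fasta: str = ""
    pssm: str = ""
    labels: str = ""
    orthologs: str = ""
    outdir: str = "."
    weight: float = 1.0
    q: float = 0.005
    threshold: float = 0.6
    window_size: int = 500
    step: int = 250
    smoothing: float = 0.5
    max_iter: int = 500
    tol: float = 1e-6
    seed: int = 0
    n_restarts: int = 1
    provenance: dict = field(default_factory=dict)

    def seq_params(self) -> SequenceModelParams:
        return SequenceModelParams(q=self.q, threshold=self.threshold)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def validate_paths(self) -> None:
        for name in ("tree", "fasta", "pssm", "labels", "orthologs"):
            p = getattr(self, name)
            if p and not Path(p).exists():
                raise FileNotFoundError(f"config path {name} = {p!r} does not exist")

    def checksum(self) -> str:
        payload = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def read_inputs(config: RunConfig) -> InputBundle:
    """Load and cross-validate all inputs.

    Every ortholog-map entry must have a promoter sequence and a cluster
    label in every species; groups failing this are dropped with a logged
    count.
    """
    config.validate_paths()
    tree = read_tree(config.tree)
    pssm = read_pssm(config.pssm)
    promoters = read_promoters(config.fasta)
    labels = read_labels(config.labels)
    omap = read_ortholog_map(config.orthologs)
    species = tree.leaves
    missing_sp = [sp for sp in species if sp not in omap.columns]
    if missing_sp:
        raise ValueError(f"ortholog map lacks columns for species {missing_sp}")
    records: list[GroupInput] = []
    dropped = 0
    for gid, row in omap.iterrows():
        genes = {sp: str(row[sp]) for sp in species}
        ok = all(
            sp in promoters and genes[sp] in promoters[sp]
            and sp in labels and genes[sp] in labels[sp]
            for sp in species
        )
        if not ok:
            dropped += 1
            continue
        records.append(
            GroupInput(
                group_id=str(gid),
                genes=genes,
                sequences={sp: promoters[sp][genes[sp]] for sp in species},
                labels={sp: labels[sp][genes[sp]] for sp in species},
            )
        )
    if dropped:
        log.warning("dropped %d ortholog groups lacking a sequence or label in some species", dropped)
    if not records:
        raise ValueError("no complete ortholog groups after cross-validation of inputs")
    return InputBundle(tree=tree, pssm=pssm, records=records, n_dropped=dropped)


# ----------------------------------------------------------------------
# results
# ----------------------------------------------------------------------


def write_results(path, posteriors: Sequence[GroupPosterior], groups: Sequence[OrthologGroup]) -> None:
    """Per-group inference table: gene ids, MAP states, marginals, category."""
    by_id = {g.group_id: g for g in groups}
    with open(path, "w") as fh:
        species = list(posteriors[0].species)
        cols = ["group"]
        cols += [f"gene_{sp}" for sp in species]
        cols += [f"state_{sp}" for sp in species]
        cols += [f"marginal_{sp}" for sp in species]
        cols.append("category")
        fh.write("#" + "\t".join(cols) + "\n")
        for p in posteriors:
            g = by_id[p.group_id]
            row = [p.group_id]
            row += [g.genes[sp] for sp in species]
            row += [str(p.map_config[sp]) for sp in species]
            row += [f"{p.marginal[sp]:.6f}" for sp in species]
            row.append(classify_conservation(p.map_config))
            fh.write("\t".join(row) + "\n")


def read_results(path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline()
    if not header.startswith("#"):
        raise ValueError(f"{path}: expected '#'-prefixed header")
    cols = header.lstrip("#").strip().split("\t")
    return pd.read_csv(path, sep="\t", comment="#", header=None, names=cols)


def write_scans(path, scans: Mapping[str, MotifScanSummary]) -> None:
    """BED-like hit table (0-based half-open) plus per-window summary columns."""
    with open(path, "w") as fh:
        fh.write("# seq_id\tstart\tend\tstrand\tscore\tn_motifs\tn_background\tlog_r\n")
        for seq_id in sorted(scans):
            s = scans[seq_id]
            if s.hits:
                for h in s.hits:
                    fh.write(
                        f"{seq_id}\t{h.start}\t{h.end}\t{h.strand}\t{h.score:.4f}"
                        f"\t{s.n_motifs}\t{s.n_background}\t{s.log_r:.4f}\n"
                    )
            else:
                fh.write(f"{seq_id}\t{s.start}\t{s.end}\t.\tNA\t0\t{s.n_background}\t0.0\n")


def write_truth(path, truth: Sequence[Mapping[str, int]], group_ids: Sequence[str]) -> None:
    species = sorted(truth[0])
    with open(path, "w") as fh:
        fh.write("#group\t" + "\t".join(species) + "\n")
        for gid, cfg in zip(group_ids, truth):
            fh.write(gid + "\t" + "\t".join(str(int(cfg[sp])) for sp in species) + "\n")


def read_truth(path) -> tuple[list[str], list[dict[str, int]]]:
    with open(path) as fh:
        header = fh.readline()
    if not header.startswith("#"):
        raise ValueError(f"{path}: expected '#'-prefixed header")
    cols = header.lstrip("#").strip().split("\t")
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=cols, dtype=str)
    species = cols[1:]
    ids = df[cols[0]].tolist()
    configs = [{sp: int(row[sp]) for sp in species} for _, row in df.iterrows()]
    return ids, configs


# ----------------------------------------------------------------------
# parameter serialization
# ----------------------------------------------------------------------


def params_to_dict(params: ModelParams) -> dict:
    return {
        "rates": {
            "lam": float(params.rates.lam),
            "mu": float(params.rates.mu),
            "pi_root": float(params.rates.pi_root),
        },
        "seq": {
            "q": float(params.seq.q),
            "threshold": float(params.seq.threshold),
            "threshold_is_relative": bool(params.seq.threshold_is_relative),
        },
        "expr": {
            "theta0": {sp: [float(x) for x in th] for sp, th in params.expr.theta0.items()},
            "theta1": {sp: [float(x) for x in th] for sp, th in params.expr.theta1.items()},
        },
        "weight": float(params.weight),
        "use_sequence": bool(params.use_sequence),
    }


def params_from_dict(data: Mapping) -> ModelParams:
    return ModelParams(
        rates=RateParams(**data["rates"]),
        seq=SequenceModelParams(**data["seq"]),
        expr=ExpressionParams(
            theta0={sp: np.asarray(v, float) for sp, v in data["expr"]["theta0"].items()},
            theta1={sp: np.asarray(v, float) for sp, v in data["expr"]["theta1"].items()},
        ),
        weight=float(data.get("weight", 1.0)),
        use_sequence=bool(data.get("use_sequence", True)),
    )


def save_params(path, params: ModelParams) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params_to_dict(params), fh, sort_keys=True)


def load_params(path) -> ModelParams:
    with open(path) as fh:
        return params_from_dict(yaml.safe_load(fh))
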