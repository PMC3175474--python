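"""Readers, writers, run configuration and result serialization.

File formats: FASTA (in-frame nucleotide) via Biopython, Newick via
dendropy, per-site tables as TSV with 1-based codon positions, model fits
and test summaries as JSON, configuration as YAML.  Triplets containing
gaps, ambiguity codes or stop codons are masked to missing data at read
time (with a logged count) so per-site methods always report every codon
column of the alignment.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetics import CodonAlignment, GeneticCode, universal_code
from .trees import Phylogeny
from .clades import PartitionSpec

logger = logging.getLogger("selcontrast")

#: mature S-RNase regions by 1-based codon position (inclusive): the two
#: hypervariable regions, conserved blocks C3/C4 and variable blocks V1/V2
SRNASE_REGIONS = {
    "HVa": (1, 38),
    "HVb": (44, 62),
    "C3": (63, 68),
    "V1": (69, 84),
    "C4": (85, 93),
    "V2": (94, 131),
}


def annotate_region(site: int) -> str | None:
    """Region label of a 1-based codon position (None between regions)."""
    for name, (lo, hi) in SRNASE_REGIONS.items():
        if lo <= site <= hi:
            return name
    return None


# ---------------------------------------------------------------------------
# Sequence / tree IO
# ---------------------------------------------------------------------------

def read_codon_fasta(path, code: GeneticCode | None = None) -> CodonAlignment:
    """Read an in-frame nucleotide FASTA as a codon alignment.

    Raises on ragged lengths or lengths not divisible by 3, naming the
    offending record; gap/ambiguity/stop triplets are masked with a logged
    count.
    """
    code = code or universal_code()
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        s = str(rec.seq)
        if len(s) % 3 != 0:
            raise ValueError(
                f"record {rec.id!r}: length {len(s)} not divisible by 3")
        if rec.id in seqs:
            raise ValueError(f"duplicate record id {rec.id!r}")
        seqs[rec.id] = s
    if not seqs:
        raise ValueError(f"no FASTA records in {path}")
    aln, n_masked = CodonAlignment.from_sequences(seqs, code)
    if n_masked:
        logger.warning("%s: masked %d gap/ambiguous/stop triplets as missing",
                       path, n_masked)
    return aln


def write_codon_fasta(aln: CodonAlignment, path) -> None:
    records = [SeqRecord(Seq(seq), id=lab, description="")
               for lab, seq in aln.to_sequences().items()]
    SeqIO.write(records, str(path), "fasta")


def read_newick(path) -> Phylogeny:
    tree = Phylogeny.from_newick(str(path))
    if not tree.has_lengths:
        logger.info("%s: tree has no branch lengths; they will be estimated",
                    path)
    return tree


def write_newick(tree: Phylogeny, path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


def read_clade_file(path, tree: Phylogeny) -> PartitionSpec:
    """Clade membership file: one taxon label per line; '#' comments.

    Labels are validated against the tree and monophyly is checked (the
    stem branch is resolved by the returned spec).
    """
    taxa = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            taxa.append(line)
    unknown = sorted(set(taxa) - set(tree.labels))
    if unknown:
        raise ValueError(f"clade file lists unknown taxa: {unknown}")
    spec = PartitionSpec(tuple(taxa))
    spec.resolve(tree)  # raises if not monophyletic
    return spec


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RunConfig:
    """Resolved options of one analysis run; serialized next to outputs."""

    nuc_model: str = "GTR"            # or 'HKY'
    freq_mode: str = "F3x4"           # or 'F61'
    alpha: float = 0.05               # per-site significance threshold
    screen_posterior: float = 0.95    # differential-call screening threshold
    chain_iterations: int = 500_000
    chain_thin: int = 100
    chain_burn_in: int = 50_000
    n_ratio_pairs: int = 10_000
    seed: int = 0
    out_dir: str = "."

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self),
                                             sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


# ---------------------------------------------------------------------------
# Result writing
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()
                if not k.startswith("_")}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_results(tables: dict, out_dir, config: RunConfig | None = None) -> dict:
    """Write a dict of results: DataFrames as TSV, everything else as JSON.

    Returns a name -> path mapping; the resolved config (if given) is
    stored alongside as ``config.yaml``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, obj in tables.items():
        if isinstance(obj, pd.DataFrame):
            p = out / f"{name}.tsv"
            obj.to_csv(p, sep="\t", index=False, float_format="%.6g")
        else:
            p = out / f"{name}.json"
            p.write_text(json.dumps(_jsonable(obj), indent=2, allow_nan=True))
        written[name] = p
    if config is not None:
        config.to_yaml(out / "config.yaml")
        written["config"] = out / "config.yaml"
    return written
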