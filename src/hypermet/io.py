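"""Readers and writers for the flat interchange formats.

Associations, pairs, matrices, rankings and id maps travel as TSV;
protein sequences as FASTA; the GO subset as OBO (``[Term]`` stanzas with
``id:``, ``is_a:`` and ``relationship: part_of`` lines); reports and
sidecars as JSON.  Duplicate rows are deduplicated with a logged count;
malformed lines fail with the file name and line number.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import obonet

from .catalog import EntityCatalog
from .godag import GoDag
from .hypergraph import AssociationTables
from .similarity import Fingerprint, SimilarityMatrix
from .hgnn import EmbeddingSet
from .synthetic import SynthConfig, SynthWorld

log = logging.getLogger("hypermet")

ASSOCIATION_FILES = {
    "disease_metabolite": "disease_metabolite.tsv",
    "disease_go": "disease_go.tsv",
    "protein_go": "protein_go.tsv",
    "metabolite_protein": "metabolite_protein.tsv",
}


def _read_tsv_rows(path: Path, n_cols: int, header: tuple[str, ...] | None = None
                   ) -> list[tuple[str, ...]]:
    rows: list[tuple[str, ...]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = tuple(line.split("\t"))
            if len(parts) != n_cols:
                raise ValueError(
                    f"{path}:{lineno}: expected {n_cols} tab-separated columns, "
                    f"got {len(parts)}"
                )
            if lineno == 1 and header is not None and parts == header:
                continue
            rows.append(parts)
    return rows


def _dedupe(rows: list, what: str, path: Path) -> list:
    unique = list(dict.fromkeys(rows))
    if len(unique) != len(rows):
        log.info("deduplicated %d duplicate %s rows in %s",
                 len(rows) - len(unique), what, path)
    return unique


def read_associations(path: str | Path) -> list[tuple[str, str]]:
    """One 2-column TSV with header ``source_id<TAB>target_id``."""
    path = Path(path)
    rows = _read_tsv_rows(path, 2, header=("source_id", "target_id"))
    return _dedupe(rows, "association", path)


def write_associations(path: str | Path, rows: list[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        fh.write("source_id\ttarget_id\n")
        for a, b in rows:
            fh.write(f"{a}\t{b}\n")


def read_association_tables(directory: str | Path) -> AssociationTables:
    directory = Path(directory)
    kwargs = {}
    for attr, fname in ASSOCIATION_FILES.items():
        fpath = directory / fname
        kwargs[attr] = read_associations(fpath) if fpath.exists() else []
    return AssociationTables(**kwargs)


def write_association_tables(directory: str | Path, tables: AssociationTables) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for attr, fname in ASSOCIATION_FILES.items():
        write_associations(directory / fname, getattr(tables, attr))


def read_smiles(path: str | Path) -> dict[str, str]:
    """TSV ``metabolite_id<TAB>smiles``."""
    path = Path(path)
    rows = _dedupe(_read_tsv_rows(path, 2), "smiles", path)
    return dict(rows)


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA with record id = protein id."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, sequences: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for pid, seq in sequences.items():
            fh.write(f">{pid}\n{seq}\n")


def read_obo(path: str | Path) -> GoDag:
    """OBO subset via obonet; keeps is_a and part_of parent links."""
    graph = obonet.read_obo(str(path))
    terms = list(graph.nodes)
    links: list[tuple[str, str]] = []
    for child, parent, key in graph.edges(keys=True):
        if key in ("is_a", "part_of"):
            links.append((child, parent))
    return GoDag.from_edges(terms, links)


def write_obo(path: str | Path, dag: GoDag) -> None:
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: go\n")
        for term in dag.terms:
            fh.write(f"\n[Term]\nid: {term}\nname: {term}\n")
            for parent in dag.parents(term):
                fh.write(f"is_a: {parent}\n")


@dataclass
class IdMap:
    """source_id -> target_id harmonization mapping (e.g. onto MONDO ids)."""

    mapping: dict[str, str]
    provenance: str = ""

    def __post_init__(self) -> None:
        # construction from rows enforces one target per source
        pass


def read_idmap(path: str | Path, provenance: str = "") -> IdMap:
    """3-column TSV triples ``source_id<TAB>relation<TAB>target_id``;
    conflicting rows for one source are an error."""
    path = Path(path)
    rows = _dedupe(_read_tsv_rows(path, 3), "id-map", path)
    mapping: dict[str, str] = {}
    for src, _, dst in rows:
        if src in mapping and mapping[src] != dst:
            raise ValueError(
                f"{path}: source id {src!r} maps to both "
                f"{mapping[src]!r} and {dst!r}"
            )
        mapping[src] = dst
    return IdMap(mapping, provenance or str(path))


def apply_idmap_catalog(catalog: EntityCatalog, idmap: IdMap
                        ) -> tuple[EntityCatalog, list[str]]:
    """Harmonize catalog ids; returns (new catalog, unmapped ids)."""
    out = EntityCatalog()
    unmapped = []
    for eid, (etype, label) in catalog.entries.items():
        if eid not in idmap.mapping:
            unmapped.append(eid)
        out.add(idmap.mapping.get(eid, eid), etype, label)
    return out, unmapped


def apply_idmap(
    rows: list[tuple[str, str]], idmap: IdMap
) -> tuple[list[tuple[str, str]], list[str]]:
    """Replace every mapped id; return (harmonized rows, unmapped ids).

    Applying the result a second time changes nothing (idempotent as long
    as map targets are not themselves map sources with different targets).
    Collisions created by the mapping are deduplicated with a warning.
    """
    unmapped: list[str] = []
    out: list[tuple[str, str]] = []
    for a, b in rows:
        for x in (a, b):
            if x not in idmap.mapping:
                unmapped.append(x)
        out.append((idmap.mapping.get(a, a), idmap.mapping.get(b, b)))
    unique = list(dict.fromkeys(out))
    if len(unique) != len(out):
        log.warning("id mapping collapsed %d rows into duplicates; deduplicated",
                    len(out) - len(unique))
    return unique, list(dict.fromkeys(unmapped))


# ---------------------------------------------------------------------------
# Matrices, embeddings, worlds


def write_similarity_matrix(path: str | Path, m: SimilarityMatrix) -> None:
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(m.labels) + "\n")
        for label, row in zip(m.labels, m.values):
            fh.write(label + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


def read_similarity_matrix(path: str | Path) -> SimilarityMatrix:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        labels = header[1:]
        values = []
        row_labels = []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            row_labels.append(parts[0])
            values.append([float(v) for v in parts[1:]])
    if row_labels != labels:
        raise ValueError(f"{path}: row labels do not match column labels")
    return SimilarityMatrix(labels, np.array(values))


def write_embeddings(path: str | Path, emb: EmbeddingSet,
                     seed: int | None = None, config: dict | None = None) -> None:
    """TSV of vectors plus a JSON sidecar (dim, role, seed, config hash)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("entity_id\t" + "\t".join(f"v{i}" for i in range(emb.dim)) + "\n")
        for eid, vec in zip(emb.ids, emb.vectors):
            fh.write(eid + "\t" + "\t".join(f"{v:.10g}" for v in vec) + "\n")
    sidecar = {
        "dim": emb.dim,
        "role": emb.role,
        "seed": seed,
        "config_hash": config_hash(config or {}),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def read_embeddings(path: str | Path) -> EmbeddingSet:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    ids, vectors = [], []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            ids.append(parts[0])
            vectors.append([float(v) for v in parts[1:]])
    return EmbeddingSet(ids, np.array(vectors), role=sidecar["role"])


def write_pairs(path: str | Path, pairs) -> None:
    """TSV ``disease_id<TAB>metabolite_id<TAB>label``."""
    with open(path, "w") as fh:
        fh.write("disease_id\tmetabolite_id\tlabel\n")
        for (d, m), y in zip(pairs.pairs, pairs.labels):
            fh.write(f"{d}\t{m}\t{int(y)}\n")


def read_pairs(path: str | Path):
    from .association import LabeledPairSet

    path = Path(path)
    rows = _read_tsv_rows(path, 3, header=("disease_id", "metabolite_id", "label"))
    ds = [r[0] for r in rows]
    ms = [r[1] for r in rows]
    labels = np.array([int(r[2]) for r in rows])
    return LabeledPairSet(ds, ms, labels)


def write_fingerprints(path: str | Path, fps: dict[str, Fingerprint]) -> None:
    """TSV ``metabolite_id<TAB>n_bits<TAB>comma-joined bit positions``."""
    with open(path, "w") as fh:
        fh.write("metabolite_id\tn_bits\tbits\n")
        for mid, fp in fps.items():
            bits = ",".join(str(b) for b in sorted(fp.bits))
            fh.write(f"{mid}\t{fp.n_bits}\t{bits}\n")


def read_fingerprints(path: str | Path) -> dict[str, Fingerprint]:
    path = Path(path)
    rows = _read_tsv_rows(path, 3, header=("metabolite_id", "n_bits", "bits"))
    out: dict[str, Fingerprint] = {}
    for mid, n_bits, bits in rows:
        positions = [int(b) for b in bits.split(",")] if bits else []
        out[mid] = Fingerprint.from_bits(positions, int(n_bits))
    return out


def write_world(directory: str | Path, world: SynthWorld) -> None:
    """Export a world in the exact pipeline input formats, plus ground truth."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_association_tables(directory, world.tables)
    write_fasta(directory / "proteins.fasta", world.sequences)
    write_obo(directory / "go.obo", world.godag)
    write_fingerprints(directory / "fingerprints.tsv", world.fingerprints)
    with open(directory / "modules.tsv", "w") as fh:
        fh.write("entity_id\tmodule\n")
        for eid, mod in world.module_of.items():
            fh.write(f"{eid}\t{mod}\n")
    with open(directory / "catalog.tsv", "w") as fh:
        fh.write("entity_id\tentity_type\n")
        for eid, etype in world.catalog.iter_typed():
            fh.write(f"{eid}\t{etype}\n")
    (directory / "config.json").write_text(
        json.dumps(dataclasses.asdict(world.config), indent=2)
    )


def read_world(directory: str | Path) -> SynthWorld:
    directory = Path(directory)
    tables = read_association_tables(directory)
    sequences = read_fasta(directory / "proteins.fasta")
    godag = read_obo(directory / "go.obo")
    fingerprints = read_fingerprints(directory / "fingerprints.tsv")
    module_rows = _read_tsv_rows(directory / "modules.tsv", 2,
                                 header=("entity_id", "module"))
    module_of = {eid: int(mod) for eid, mod in module_rows}
    catalog = EntityCatalog()
    for eid, etype in _read_tsv_rows(directory / "catalog.tsv", 2,
                                     header=("entity_id", "entity_type")):
        catalog.add(eid, etype)
    config = SynthConfig(**json.loads((directory / "config.json").read_text()))
    return SynthWorld(catalog, tables, fingerprints, sequences, godag,
                      module_of, config)


def config_hash(config: dict) -> str:
    """Short stable hash identifying a run configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
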