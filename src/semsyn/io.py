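"""Plain-text readers and writers for the pipeline's external formats.

Everything here is deliberately simple and text-based: CoNLL-U for token
annotations (FORM, UPOS, FEATS columns), one bracketed tree per line,
TSV tables for timings / feature streams / voxel grids / maps, and
delimited numeric matrices with JSON sidecars for BOLD runs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .corpus import FeatureStream, ParseTree

_CONLLU_COLS = ["ID", "FORM", "LEMMA", "UPOS", "XPOS", "FEATS",
                "HEAD", "DEPREL", "DEPS", "MISC"]


def parse_conllu(text: str) -> list[list[tuple[str, str, str]]]:
    """Parse CoNLL-U text into sentences of (FORM, UPOS, FEATS) tuples.

    Multiword-token ranges and empty nodes (ids containing ``-`` or ``.``)
    are skipped, as are comment lines.
    """
    sentences: list[list[tuple[str, str, str]]] = []
    current: list[tuple[str, str, str]] = []
    for line in text.splitlines():
        line = line.rstrip("\n")
        if not line.strip():
            if current:
                sentences.append(current)
                current = []
            continue
        if line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 6:
            raise ValueError(f"malformed CoNLL-U line: {line!r}")
        tok_id = fields[0]
        if "-" in tok_id or "." in tok_id:
            continue
        current.append((fields[1], fields[3], fields[5]))
    if current:
        sentences.append(current)
    return sentences


def format_conllu(sentences: list[list[tuple[str, str, str]]]) -> str:
    """Serialize sentences of (FORM, UPOS, FEATS) tuples as CoNLL-U text."""
    blocks = []
    for sent in sentences:
        lines = []
        for i, (form, upos, feats) in enumerate(sent, start=1):
            row = [str(i), form, "_", upos, "_", feats or "_", "0", "dep", "_", "_"]
            lines.append("\t".join(row))
        blocks.append("\n".join(lines))
    return "\n\n".join(blocks) + "\n"


def read_trees(text: str) -> list[ParseTree]:
    """One bracketed tree per non-empty line."""
    return [ParseTree(line) for line in text.splitlines() if line.strip()]


def format_trees(trees: list[ParseTree]) -> str:
    return "\n".join(t.bracketed for t in trees) + "\n"


def read_timings(source) -> pd.DataFrame:
    """Timing table TSV with header ``token  onset  offset  run``."""
    df = pd.read_csv(source, sep="\t", dtype={"token": str},
                     float_precision="round_trip")
    required = {"token", "onset", "offset", "run"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"timing table missing columns: {sorted(missing)}")
    return df


def write_timings(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_stream(stream: FeatureStream, path) -> None:
    """Feature stream as TSV ``position  symbol  source_index``."""
    df = pd.DataFrame({
        "position": np.arange(len(stream)),
        "symbol": stream.symbols,
        "source_index": stream.alignment,
    })
    with open(path, "w") as fh:
        fh.write(f"# mode={stream.mode}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_stream(path) -> FeatureStream:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("# mode="):
            raise ValueError(f"{path}: missing stream mode header")
        mode = header.split("=", 1)[1]
        df = pd.read_csv(fh, sep="\t", dtype={"symbol": str})
    return FeatureStream(mode=mode, symbols=df["symbol"].tolist(),
                         alignment=df["source_index"].astype(int).tolist())


def write_bold_run(matrix: np.ndarray, path, *, tr: float, subject: str,
                   run_id: int) -> None:
    """Scans × voxels matrix as TSV plus a JSON sidecar of acquisition facts."""
    path = Path(path)
    np.savetxt(path, np.asarray(matrix), delimiter="\t")
    sidecar = {"TR": tr, "subject": subject, "run": run_id,
               "n_scans": int(matrix.shape[0]), "n_voxels": int(matrix.shape[1])}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_bold_run(path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    matrix = np.loadtxt(path, delimiter="\t", ndmin=2)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return matrix, sidecar


def write_grid(grid, path) -> None:
    grid.to_frame().to_csv(path, sep="\t", index=False)


def read_grid(path):
    from .grids import VoxelGrid
    return VoxelGrid.from_frame(pd.read_csv(path, sep="\t"))


def write_map(vmap, path, column: str = "value") -> None:
    vmap.to_frame(column).to_csv(path, sep="\t", index=False)


def write_embedding_matrix(X: np.ndarray, path, *, sidecar: dict | None = None) -> None:
    """Embedding matrix as TSV with dimension-name header and JSON sidecar."""
    path = Path(path)
    d = X.shape[1] if X.ndim == 2 else 0
    header = "\t".join(f"dim{i}" for i in range(d))
    np.savetxt(path, np.asarray(X), delimiter="\t", header=header, comments="")
    if sidecar is not None:
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_embedding_matrix(path) -> np.ndarray:
    return np.loadtxt(path, delimiter="\t", skiprows=1, ndmin=2)


def write_vocabulary(vocab, path) -> None:
    """Syntactic vocabulary as TSV ``symbol  id`` (stable id order)."""
    from .corpus import triplet_symbol
    rows = sorted(vocab.triplet_to_id.items(), key=lambda kv: kv[1])
    df = pd.DataFrame({"symbol": [triplet_symbol(*t) for t, _ in rows],
                       "id": [i for _, i in rows]})
    df.to_csv(path, sep="\t", index=False)


def read_vocabulary(path):
    """Rebuild a SyntacticVocabulary from its TSV form."""
    from .corpus import SyntacticVocabulary
    df = pd.read_csv(path, sep="\t", dtype={"symbol": str})
    mapping = {}
    for sym, vid in zip(df["symbol"], df["id"]):
        pos, *feats, ncn = sym.split("|")
        mapping[(pos, "|".join(feats), int(ncn))] = int(vid)
    return SyntacticVocabulary(triplet_to_id=mapping, oov_id=len(mapping))


def write_group_result(result, grid, path) -> None:
    """Group map as TSV ``voxel_id  t  z  p  significant``."""
    pd.DataFrame({
        "voxel_id": grid.voxel_ids,
        "t": result.t.values,
        "z": result.z.values,
        "p": result.p.values,
        "significant": result.mask.astype(int),
    }).to_csv(path, sep="\t", index=False)


def write_probe_task(task, path) -> None:
    """Probe task as TSV ``token_index  label  run  eligible``."""
    pd.DataFrame({
        "token_index": np.arange(task.labels.shape[0]),
        "label": task.labels,
        "run": task.runs,
        "eligible": task.eligible.astype(int),
    }).to_csv(path, sep="\t", index=False)


def read_probe_task(path):
    from .probes import ProbeTask
    df = pd.read_csv(path, sep="\t")
    return ProbeTask(labels=df["label"].to_numpy(),
                     runs=df["run"].to_numpy(),
                     eligible=df["eligible"].to_numpy(bool))


# -- optional NIfTI adapter (nibabel) ---------------------------------------


def read_nifti_run(img_path, grid, *, tr: float, subject: str = "sub-01",
                   run_id: int = 1, voxel_size_mm=(4.0, 4.0, 4.0)):
    """Read a 4-D NIfTI into a BoldRun restricted to the grid's voxels.

    Voxel coordinates are matched on the lattice (coordinates are taken as
    voxel-space mm relative to the grid origin); requires nibabel.
    """
    import nibabel as nib
    from .encoding import BoldRun
    img = nib.load(str(img_path))
    data = np.asarray(img.dataobj)
    idx, _ = grid.lattice_indices(voxel_size_mm)
    series = data[idx[:, 0], idx[:, 1], idx[:, 2], :].T  # scans × voxels
    return BoldRun(data=series.astype(float), tr=tr, subject=subject,
                   run_id=run_id, grid=grid)


def write_nifti_map(vmap, path, voxel_size_mm=(4.0, 4.0, 4.0)) -> None:
    """Write a voxel map as a 3-D NIfTI mirroring the grid metadata."""
    import nibabel as nib
    idx, shape = vmap.grid.lattice_indices(voxel_size_mm)
    vol = np.full(shape, np.nan)
    vol[idx[:, 0], idx[:, 1], idx[:, 2]] = vmap.values
    affine = np.diag(list(np.broadcast_to(voxel_size_mm, (3,))) + [1.0])
    nib.save(nib.Nifti1Image(vol, affine), str(path))
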