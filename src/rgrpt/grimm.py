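"""Reader/writer for GRIMM-style genome order files.

Format: a ``>name`` header line per genome, followed by one line per
chromosome of whitespace-separated signed integers terminated by ``$``
(linear chromosome).  Lines starting with ``#`` are comments.  Reading a
written file reproduces it byte for byte.
"""

from __future__ import annotations

import io
from pathlib import Path
from typing import Iterable, Union

from .genome import Genome


def parse_genomes(text: str) -> list[Genome]:
    genomes: list[Genome] = []
    name: str | None = None
    chroms: list[tuple[int, ...]] = []

    def flush() -> None:
        nonlocal name, chroms
        if name is not None:
            if not chroms:
                raise ValueError(f"genome {name!r} has no chromosomes")
            genomes.append(Genome(name, tuple(chroms)))
        name, chroms = None, []

    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith(">"):
            flush()
            name = line[1:].strip()
            if not name:
                raise ValueError(f"line {lineno}: empty genome name")
            continue
        if name is None:
            raise ValueError(f"line {lineno}: chromosome before any '>' header")
        tokens = line.split()
        if tokens[-1] != "$":
            raise ValueError(f"line {lineno}: chromosome not terminated by '$'")
        try:
            blocks = tuple(int(t) for t in tokens[:-1])
        except ValueError as exc:
            raise ValueError(f"line {lineno}: bad block label") from exc
        if not blocks:
            raise ValueError(f"line {lineno}: empty chromosome")
        chroms.append(blocks)
    flush()
    if not genomes:
        raise ValueError("no genomes found")
    return genomes


def format_genomes(genomes: Iterable[Genome]) -> str:
    out = io.StringIO()
    for g in genomes:
        out.write(f">{g.name}\n")
        for chrom in g.chromosomes:
            out.write(" ".join(str(v) for v in chrom) + " $\n")
    return out.getvalue()


def read_genomes(path: Union[str, Path]) -> list[Genome]:
    return parse_genomes(Path(path).read_text())


def write_genomes(genomes: Iterable[Genome], path: Union[str, Path]) -> None:
    Path(path).write_text(format_genomes(genomes))
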