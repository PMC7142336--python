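"""Reading and writing HH-suite ``.hhm`` profile HMMs.

An ``.hhm`` document stores, for every residue of the query protein, 20
match-emission scores in the integer score space ``x = -1000 * log2(p)``
(``*`` meaning zero probability).  This module decodes those scores back to
emission probabilities with ``f(x) = 2**(-x/1000)`` and exposes the profile
as an L x 20 matrix of values in [0, 1] — the only part of the file the
downstream feature descriptors consume.  Only the 20 residue-indexed match
columns are kept; the transition/diversity columns are ignored.
"""

from __future__ import annotations

import io
import logging
import math
import subprocess
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, TextIO, Union

import numpy as np

logger = logging.getLogger(__name__)

#: Match-emission column order used by HH-suite `.hhm` headers.
RESIDUE_ORDER: tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY")

STAR = "*"


class HhmParseError(ValueError):
    """Raised when an ``.hhm`` document violates the expected structure."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


@dataclass(frozen=True)
class ParserOptions:
    """Knobs for :func:`parse_hhm`.

    star_value
        Probability substituted for the ``*`` token (no-probability marker).
    strict
        If True (default), malformed residue blocks or header inconsistencies
        abort with :class:`HhmParseError`; if False they are skipped with a
        logged warning.
    """

    star_value: float = 0.0
    strict: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.star_value <= 1.0:
            raise ValueError(f"star_value must lie in [0, 1], got {self.star_value}")


@dataclass
class HmmProfile:
    """An L x 20 matrix of transformed match-emission values for one protein.

    Rows are residue positions, columns follow ``residue_order`` (the letter
    order of the source file's ``HMM`` header line).  Every entry lies in
    [0, 1]; it is the emission probability decoded from the integer score.
    """

    sequence_id: str
    matrix: np.ndarray
    residue_order: tuple[str, ...] = RESIDUE_ORDER
    sequence: str | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 20:
            raise ValueError(
                f"profile matrix must be L x 20, got shape {self.matrix.shape}"
            )
        if self.matrix.shape[0] < 1:
            raise ValueError("profile must contain at least one residue row")
        if not np.isfinite(self.matrix).all():
            raise ValueError("profile matrix contains non-finite values")
        if self.matrix.min() < 0.0 or self.matrix.max() > 1.0:
            raise ValueError("profile values must lie in [0, 1]")
        order = tuple(self.residue_order)
        if len(order) != 20 or len(set(order)) != 20:
            raise ValueError("residue_order must list 20 distinct letters")
        self.residue_order = order
        if self.sequence is not None and len(self.sequence) != self.matrix.shape[0]:
            raise ValueError("sequence length does not match matrix rows")

    @property
    def length(self) -> int:
        return int(self.matrix.shape[0])


def transform_score(x: Union[int, str]) -> float:
    """Decode one integer emission score to a probability, ``2**(-x/1000)``.

    The ``*`` token (HH-suite's "no probability") maps to 0.  Scores are
    non-negative by construction (probabilities never exceed 1); a negative
    input is rejected.
    """
    if isinstance(x, str):
        if x == STAR:
            return 0.0
        x = int(x)
    if x < 0:
        raise ValueError(f"emission score must be non-negative, got {x}")
    return 2.0 ** (-x / 1000.0)


def inverse_transform(h: float) -> str:
    """Map a probability back to the integer score token (``*`` for h = 0)."""
    if not 0.0 <= h <= 1.0:
        raise ValueError(f"probability must lie in [0, 1], got {h}")
    if h == 0.0:
        return STAR
    return str(int(round(-1000.0 * math.log2(h))))


def _as_lines(source: Union[str, Path, TextIO]) -> tuple[str, list[str]]:
    """Return (default id, lines) for a path, a document string or a stream."""
    if isinstance(source, Path):
        return source.stem, source.read_text().splitlines()
    if isinstance(source, str):
        if "\n" not in source and Path(source).is_file():
            p = Path(source)
            return p.stem, p.read_text().splitlines()
        return "profile", source.splitlines()
    name = getattr(source, "name", "profile")
    return Path(str(name)).stem, source.read().splitlines()


def _is_emission_line(tokens: list[str]) -> bool:
    return (
        len(tokens) >= 2
        and len(tokens[0]) == 1
        and tokens[0].isalpha()
        and tokens[1].isdigit()
    )


def parse_hhm(
    source: Union[str, Path, TextIO], options: ParserOptions | None = None
) -> HmmProfile:
    """Parse one ``.hhm`` document into an :class:`HmmProfile`.

    The document must contain a header section ending at the line beginning
    ``#``, an ``HMM`` column-header line naming the 20 match columns, residue
    blocks (emission line + transition line), and the ``//`` terminator.
    Emission scores are decoded with :func:`transform_score`.
    """
    opts = options or ParserOptions()
    default_id, lines = _as_lines(source)

    seq_id = default_id
    declared_length: int | None = None
    header_order: tuple[str, ...] | None = None
    hash_seen = False
    hmm_line_idx: int | None = None

    for i, line in enumerate(lines):
        stripped = line.strip()
        if stripped.startswith("NAME"):
            parts = stripped.split(maxsplit=1)
            if len(parts) == 2:
                seq_id = parts[1].split()[0]
        elif stripped.startswith("LENG"):
            parts = stripped.split()
            if len(parts) >= 2 and parts[1].isdigit():
                declared_length = int(parts[1])
        elif stripped.startswith("#"):
            hash_seen = True
        elif stripped.startswith("HMM") and hash_seen:
            tokens = stripped.split()
            if len(tokens) >= 21:
                header_order = tuple(tokens[1:21])
                hmm_line_idx = i
                break

    if not hash_seen:
        raise HhmParseError("missing '#' header separator")
    if header_order is None or hmm_line_idx is None:
        raise HhmParseError("missing 'HMM' column-header line after '#'")
    if len(set(header_order)) != 20 or any(len(a) != 1 for a in header_order):
        raise HhmParseError(
            f"HMM header must name 20 distinct residue letters, got {header_order}",
            hmm_line_idx + 1,
        )

    rows: list[list[float]] = []
    residues: list[str] = []
    terminated = False
    i = hmm_line_idx + 1
    while i < len(lines):
        stripped = lines[i].strip()
        if stripped == "//":
            terminated = True
            break
        tokens = stripped.split()
        if _is_emission_line(tokens):
            # 1 letter + 1 position + 20 scores (+ optional alignment column)
            score_tokens = tokens[2:22]
            if len(score_tokens) != 20:
                msg = (
                    f"residue block for position {tokens[1]} has "
                    f"{len(tokens) - 2} emission fields, expected 20"
                )
                if opts.strict:
                    raise HhmParseError(msg, i + 1)
                logger.warning("skipping malformed block: %s", msg)
                i += 2
                continue
            try:
                row = [
                    opts.star_value if t == STAR else transform_score(int(t))
                    for t in score_tokens
                ]
            except ValueError as exc:
                if opts.strict:
                    raise HhmParseError(str(exc), i + 1) from exc
                logger.warning("skipping malformed block at line %d: %s", i + 1, exc)
                i += 2
                continue
            rows.append(row)
            residues.append(tokens[0])
            i += 2  # emission line + transition line
        else:
            i += 1

    if not terminated:
        raise HhmParseError("missing '//' terminator")
    if not rows:
        raise HhmParseError("document contains no residue blocks")
    if opts.strict and declared_length is not None and declared_length != len(rows):
        raise HhmParseError(
            f"LENG header declares {declared_length} residues but "
            f"{len(rows)} blocks were parsed"
        )

    return HmmProfile(
        sequence_id=seq_id,
        matrix=np.array(rows, dtype=float),
        residue_order=header_order,
        sequence="".join(residues),
    )


def write_hhm(profile: HmmProfile, path: Union[str, Path, None] = None) -> str:
    """Serialize a profile to ``.hhm`` text accepted by :func:`parse_hhm`.

    Probabilities are mapped back to integer scores with
    :func:`inverse_transform` (``h = 0`` becomes ``*``), so a round trip
    reproduces the matrix to within the quantization of integer scores.
    """
    L = profile.length
    seq = profile.sequence or "A" * L
    out = io.StringIO()
    out.write("HHsearch 1.5\n")
    out.write(f"NAME  {profile.sequence_id}\n")
    out.write(f"LENG  {L} match states, {L} columns in multiple alignment\n")
    out.write("NEFF  1.0\n")
    out.write("#\n")
    out.write("NULL   " + "\t".join(["3000"] * 20) + "\n")
    out.write("HMM    " + "\t".join(profile.residue_order) + "\n")
    out.write(
        "       M->M\tM->I\tM->D\tI->M\tI->I\tD->M\tD->D\tNeff\tNeff_I\tNeff_D\n"
    )
    out.write("       0\t*\t*\t0\t*\t0\t*\t*\t*\t*\n")
    for i in range(L):
        scores = "\t".join(inverse_transform(h) for h in profile.matrix[i])
        out.write(f"{seq[i]} {i + 1}\t{scores}\t{i + 1}\n")
        out.write("       0\t*\t*\t*\t*\t*\t*\t1000\t0\t0\n\n")
    out.write("//\n")
    text = out.getvalue()
    if path is not None:
        Path(path).write_text(text)
    return text


def read_profile_dir(
    directory: Union[str, Path],
    label_file: Union[str, Path] | None = None,
    options: ParserOptions | None = None,
) -> tuple[list[HmmProfile], dict[str, int] | None]:
    """Parse every ``.hhm`` file in a directory (sorted by name).

    If ``label_file`` is given it is read as two-column tab-separated text
    (protein id, 0/1 label) and returned as a dict; ids present in only one
    of the two sources raise ``KeyError``.
    """
    directory = Path(directory)
    profiles = [parse_hhm(p, options) for p in sorted(directory.glob("*.hhm"))]
    if label_file is None:
        return profiles, None
    labels: dict[str, int] = {}
    for ln, line in enumerate(Path(label_file).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"label file line {ln}: expected 2 tab-separated fields")
        labels[parts[0]] = int(parts[1])
    missing = [p.sequence_id for p in profiles if p.sequence_id not in labels]
    if missing:
        raise KeyError(f"profiles without labels: {missing[:5]}")
    return profiles, labels


def run_hhblits(
    fasta: Union[str, Path],
    database: str,
    out_hhm: Union[str, Path],
    iterations: int = 4,
    evalue: float = 0.001,
    hhblits_bin: str = "hhblits",
    extra_args: Iterable[str] = (),
) -> HmmProfile:
    """Optional wrapper producing an ``.hhm`` profile with an external HHblits.

    Runs ``hhblits -i fasta -d database -n iterations -e evalue -ohhm out``.
    Requires HHblits and a sequence database to be installed; no part of the
    package depends on it — profiles can always be supplied as files.
    """
    cmd = [
        hhblits_bin,
        "-i", str(fasta),
        "-d", database,
        "-n", str(iterations),
        "-e", str(evalue),
        "-ohhm", str(out_hhm),
        *extra_args,
    ]
    subprocess.run(cmd, check=True)
    return parse_hhm(Path(out_hhm))
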