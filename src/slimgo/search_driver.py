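"""Optional wrapper around an external translated-search executable.

The pipeline never requires a live BLAST or DIAMOND install: any
12-column tabular file can be supplied instead.  This module only
assembles the command line (pure, testable) and shells out.
"""

from __future__ import annotations

import os
import shutil
import subprocess
from dataclasses import dataclass, field

from .formats_io import read_fasta

__all__ = ["SearchConfig", "SearchError", "build_search_command", "run_search"]

DEFAULT_NUM_THREADS = 1
DEFAULT_MAX_TARGET_SEQS = 50
DEFAULT_EVALUE = 0.001


class SearchError(RuntimeError):
    pass


@dataclass
class SearchConfig:
    """Parameters for the translated nucleotide-vs-protein search."""

    program: str = "blast"
    database_path: str = ""
    num_threads: int = DEFAULT_NUM_THREADS
    max_target_seqs: int = DEFAULT_MAX_TARGET_SEQS
    evalue_threshold: float = DEFAULT_EVALUE
    extra_args: list[str] = field(default_factory=list)
    executable: str | None = None  # override binary name (used by test stubs)

    def __post_init__(self) -> None:
        if self.program not in ("blast", "diamond"):
            raise ValueError(f"unknown search program {self.program!r}")
        if self.evalue_threshold <= 0:
            raise ValueError("evalue_threshold must be > 0")
        if self.max_target_seqs < 1:
            raise ValueError("max_target_seqs must be >= 1")
        if self.num_threads < 1:
            raise ValueError("num_threads must be >= 1")


def _fmt_evalue(e: float) -> str:
    return repr(float(e))


def build_search_command(config: SearchConfig, query: str | os.PathLike,
                         out: str | os.PathLike) -> list[str]:
    """Assemble the argv for a translated search with tabular output.

    Pure string assembly; nothing is executed.  Defaults are
    ``-num_threads 1 -max_target_seqs 50 -evalue 0.001`` (blastx) or the
    DIAMOND equivalents.
    """
    if config.program == "blast":
        argv = [
            config.executable or "blastx",
            "-query", str(query),
            "-db", str(config.database_path),
            "-out", str(out),
            "-outfmt", "6",
            "-num_threads", str(config.num_threads),
            "-max_target_seqs", str(config.max_target_seqs),
            "-evalue", _fmt_evalue(config.evalue_threshold),
        ]
    else:  # diamond
        argv = [
            config.executable or "diamond",
            "blastx",
            "--query", str(query),
            "--db", str(config.database_path),
            "--out", str(out),
            "--outfmt", "6",
            "--threads", str(config.num_threads),
            "--max-target-seqs", str(config.max_target_seqs),
            "--evalue", _fmt_evalue(config.evalue_threshold),
        ]
    argv.extend(config.extra_args)
    return argv


def run_search(fasta: str | os.PathLike, config: SearchConfig,
               out: str | os.PathLike) -> str:
    """Run the configured external search and return the hits-file path.

    Validates the query FASTA first so a malformed input never launches a
    long external job, and removes any partial output on failure.
    """
    read_fasta(fasta)  # raises on missing/empty/duplicate-id input

    executable = build_search_command(config, fasta, out)[0]
    if shutil.which(executable) is None:
        raise SearchError(
            f"search executable {executable!r} not found on PATH; either "
            f"install it or bypass the search step by supplying a "
            f"precomputed 12-column tabular hits file (--hits)")
    if config.database_path and not _database_present(config):
        raise SearchError(
            f"reference database {config.database_path!r} not found")

    argv = build_search_command(config, fasta, out)
    proc = subprocess.run(argv, capture_output=True, text=True)
    if proc.returncode != 0:
        if os.path.exists(out):
            os.unlink(out)
        raise SearchError(
            f"{config.program} exited with status {proc.returncode}: "
            f"{proc.stderr.strip()}")
    if not os.path.exists(out):
        raise SearchError(f"{config.program} produced no output file {out!r}")
    return str(out)


def _database_present(config: SearchConfig) -> bool:
    base = config.database_path
    if os.path.exists(base):
        return True
    # BLAST databases are sets of files sharing a basename prefix.
    prefix_dir = os.path.dirname(base) or "."
    prefix = os.path.basename(base)
    if not os.path.isdir(prefix_dir):
        return False
    return any(name.startswith(prefix) for name in os.listdir(prefix_dir))
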