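"""Readers and writers for the external per-chain file formats.

Covers FASTA sequences, PSI-BLAST ASCII PSSM profiles, PSIPRED ``.ss2``
secondary-structure files, DISOPRED-style per-residue disorder tables,
plain RSA/prediction TSVs, and the derivation of relative solvent
accessibility (RSA) from DSSP accessibility (ACC) values.

Positions are 1-based in every file dialect and 0-based in memory; the
conversion happens only in this module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import yaml
from Bio import SeqIO

from .errors import ConfigurationError, FormatError, LengthMismatchError

#: Canonical 20-letter amino-acid alphabet in PSI-BLAST PSSM column order.
AA_ALPHABET = "ARNDCQEGHILKMFPSTWYV"
STANDARD_AA = frozenset(AA_ALPHABET)


@dataclass
class PssmProfile:
    """L x 20 raw log-odds scores; columns follow :data:`AA_ALPHABET`."""

    scores: np.ndarray
    alphabet: str = AA_ALPHABET

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != len(self.alphabet):
            raise ConfigurationError(
                f"PSSM must be Lx{len(self.alphabet)}, got {self.scores.shape}"
            )

    def __len__(self) -> int:
        return self.scores.shape[0]


@dataclass
class Ss3Profile:
    """Three-state secondary structure: state string over {C,H,E} + probabilities.

    ``probs`` columns are ordered (C, H, E). Probabilities are stored verbatim
    (no renormalisation); argmax ties are broken with priority C > H > E.
    """

    states: str
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (len(self.states), 3):
            raise ConfigurationError("ss3 probs must be Lx3 matching the state string")
        if np.any((self.probs < 0) | (self.probs > 1)):
            raise FormatError("secondary-structure probabilities outside [0,1]")

    def __len__(self) -> int:
        return len(self.states)


@dataclass
class DisorderProfile:
    """Per-residue native-disorder probabilities and binarised state."""

    p_disorder: np.ndarray
    p_order: np.ndarray
    state: np.ndarray
    threshold: float = 0.5

    def __post_init__(self) -> None:
        self.p_disorder = np.asarray(self.p_disorder, dtype=float)
        self.p_order = np.asarray(self.p_order, dtype=float)
        self.state = np.asarray(self.state, dtype=int)
        if not np.allclose(self.p_disorder + self.p_order, 1.0, atol=1e-9):
            raise ConfigurationError("p_disorder + p_order must equal 1 elementwise")

    def __len__(self) -> int:
        return self.p_disorder.shape[0]


@dataclass
class RsaTrack:
    """Per-residue RSA values on a declared scale ('fraction' or 'percent')."""

    rsa: np.ndarray
    unit_scale: str = "fraction"

    def __post_init__(self) -> None:
        self.rsa = np.asarray(self.rsa, dtype=float)
        if self.unit_scale not in ("fraction", "percent"):
            raise ConfigurationError(f"unknown RSA unit scale {self.unit_scale!r}")
        if np.any(self.rsa < 0):
            raise FormatError("RSA values must be non-negative")

    @property
    def ceiling(self) -> float:
        return 1.0 if self.unit_scale == "fraction" else 100.0

    def as_fraction(self) -> np.ndarray:
        return self.rsa if self.unit_scale == "fraction" else self.rsa / 100.0

    def as_percent(self) -> np.ndarray:
        return self.rsa * 100.0 if self.unit_scale == "fraction" else self.rsa

    def __len__(self) -> int:
        return self.rsa.shape[0]


@dataclass
class ChainRecord:
    """One protein chain with its sequence and optional per-residue profiles."""

    chain_id: str
    sequence: str
    pssm: Optional[PssmProfile] = None
    ss3: Optional[Ss3Profile] = None
    disorder: Optional[DisorderProfile] = None
    rsa: Optional[RsaTrack] = None

    def __post_init__(self) -> None:
        if not self.chain_id:
            raise ConfigurationError("chain_id must be non-empty")
        if not self.sequence:
            raise FormatError(f"chain {self.chain_id!r} has an empty sequence")
        for name in ("pssm", "ss3", "disorder", "rsa"):
            prof = getattr(self, name)
            if prof is not None and len(prof) != len(self.sequence):
                raise LengthMismatchError(
                    f"chain {self.chain_id}: {name} has {len(prof)} rows, "
                    f"sequence length is {len(self.sequence)}"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class MaxAsaTable:
    """Maximum accessible surface area (A^2) per amino-acid letter.

    X falls back to the mean over the 20 standard letters.
    """

    values: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = STANDARD_AA - set(self.values)
        if missing:
            raise ConfigurationError(f"max-ASA table missing letters {sorted(missing)}")
        if any(v <= 0 for v in self.values.values()):
            raise ConfigurationError("max-ASA values must be positive")
        if "X" not in self.values:
            self.values = dict(self.values)
            self.values["X"] = float(np.mean([self.values[a] for a in AA_ALPHABET]))

    def __getitem__(self, letter: str) -> float:
        try:
            return self.values[letter]
        except KeyError:
            raise ConfigurationError(f"no max-ASA entry for residue {letter!r}") from None


def load_max_asa(path: Optional[str] = None) -> MaxAsaTable:
    """Load a max-ASA table; default is the packaged Ala-X-Ala tri-peptide set."""
    if path is None:
        text = resources.files("rsapred.data").joinpath("max_asa.yaml").read_text()
    else:
        text = Path(path).read_text()
    return MaxAsaTable({k: float(v) for k, v in yaml.safe_load(text).items()})


def _clean_sequence(raw: str, chain_id: str) -> str:
    seq = raw.upper()
    bad = sorted({c for c in seq if c not in STANDARD_AA and c != "X"})
    if bad:
        warnings.warn(
            f"chain {chain_id}: non-standard letters {bad} mapped to X", stacklevel=3
        )
        seq = "".join(c if c in STANDARD_AA or c == "X" else "X" for c in seq)
    return seq


def read_fasta(path) -> list[ChainRecord]:
    """Read a FASTA file into sequence-only :class:`ChainRecord` objects.

    Non-standard letters are mapped to X with a warning; an empty file or an
    empty sequence entry is a :class:`FormatError`.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    chains = []
    for rec in records:
        seq = str(rec.seq)
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has a zero-length sequence")
        chains.append(ChainRecord(chain_id=rec.id, sequence=_clean_sequence(seq, rec.id)))
    return chains


def write_fasta(path, chains: list[ChainRecord]) -> None:
    with open(path, "w") as fh:
        for chain in chains:
            fh.write(f">{chain.chain_id}\n")
            for i in range(0, chain.length, 60):
                fh.write(chain.sequence[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII PSSM
# ---------------------------------------------------------------------------

def read_pssm(path, L: int) -> PssmProfile:
    """Parse a PSI-BLAST ASCII PSSM into raw (un-normalised) LxN scores.

    Accepts the standard dialect: free-form header lines, then per-residue rows
    ``index letter s1 .. s20 [...]``; only the first 20 numeric columns after
    the letter are used (real PSI-BLAST output carries 20 further percentage
    columns which are ignored).
    """
    rows = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        parts = line.split()
        if len(parts) < 22 or not parts[0].isdigit():
            continue  # header / footer / column-label lines
        try:
            scores = [float(v) for v in parts[2:22]]
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric PSSM cell ({exc})") from None
        rows.append(scores)
    if len(rows) != L:
        raise LengthMismatchError(f"{path}: expected {L} PSSM rows, found {len(rows)}")
    return PssmProfile(np.array(rows, dtype=float))


def write_pssm(path, chain: ChainRecord) -> None:
    """Write a chain's PSSM in the PSI-BLAST ASCII dialect (integer-rounded)."""
    if chain.pssm is None:
        raise ConfigurationError(f"chain {chain.chain_id} has no PSSM to write")
    with open(path, "w") as fh:
        fh.write("\n")
        fh.write("Last position-specific scoring matrix computed\n")
        fh.write("      " + "  ".join(AA_ALPHABET) + "\n")
        for i, (letter, row) in enumerate(zip(chain.sequence, chain.pssm.scores), start=1):
            cells = " ".join(f"{int(round(v)):3d}" for v in row)
            fh.write(f"{i:5d} {letter} {cells}\n")
        fh.write("\n")


# ---------------------------------------------------------------------------
# PSIPRED .ss2
# ---------------------------------------------------------------------------

SS_STATES = "CHE"  # probability column order in .ss2: coil, helix, strand


def read_psipred_ss2(path, L: int) -> Ss3Profile:
    """Parse a PSIPRED ``.ss2`` file: rows of (index, residue, state, pC, pH, pE).

    Probabilities are taken verbatim — rows whose probabilities do not sum to 1
    are accepted unchanged.
    """
    states, probs = [], []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        parts = line.split()
        if len(parts) != 6 or not parts[0].isdigit():
            continue  # comment / blank / header
        if parts[2] not in SS_STATES:
            raise FormatError(f"{path}:{lineno}: unknown state {parts[2]!r}")
        try:
            triple = [float(parts[3]), float(parts[4]), float(parts[5])]
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric probability ({exc})") from None
        states.append(parts[2])
        probs.append(triple)
    if len(states) != L:
        raise LengthMismatchError(f"{path}: expected {L} ss2 rows, found {len(states)}")
    return Ss3Profile("".join(states), np.array(probs, dtype=float))


def write_psipred_ss2(path, chain: ChainRecord) -> None:
    if chain.ss3 is None:
        raise ConfigurationError(f"chain {chain.chain_id} has no ss3 profile to write")
    with open(path, "w") as fh:
        fh.write("# PSIPRED VFORMAT\n\n")
        for i, (letter, state, row) in enumerate(
            zip(chain.sequence, chain.ss3.states, chain.ss3.probs), start=1
        ):
            fh.write(
                f"{i:4d} {letter} {state}  {row[0]:6.3f} {row[1]:6.3f} {row[2]:6.3f}\n"
            )


# ---------------------------------------------------------------------------
# DISOPRED-style disorder table
# ---------------------------------------------------------------------------

def read_disopred(path, L: int, threshold: float = 0.5) -> DisorderProfile:
    """Parse a DISOPRED-style table: rows of (index, residue, mark, probability).

    ``p_order`` is derived as 1 − p_disorder; the binary state is 1 where
    p_disorder ≥ ``threshold``.
    """
    p_dis = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        parts = line.split()
        if len(parts) != 4 or not parts[0].isdigit():
            continue
        try:
            p = float(parts[3])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric probability ({exc})") from None
        if not 0.0 <= p <= 1.0:
            raise FormatError(f"{path}:{lineno}: disorder probability {p} outside [0,1]")
        p_dis.append(p)
    if len(p_dis) != L:
        raise LengthMismatchError(f"{path}: expected {L} disorder rows, found {len(p_dis)}")
    p_dis = np.array(p_dis, dtype=float)
    return DisorderProfile(
        p_disorder=p_dis,
        p_order=1.0 - p_dis,
        state=(p_dis >= threshold).astype(int),
        threshold=threshold,
    )


def write_disopred(path, chain: ChainRecord) -> None:
    if chain.disorder is None:
        raise ConfigurationError(f"chain {chain.chain_id} has no disorder profile")
    with open(path, "w") as fh:
        fh.write("#          ----- DISOPRED-style per-residue output -----\n")
        for i, (letter, state, p) in enumerate(
            zip(chain.sequence, chain.disorder.state, chain.disorder.p_disorder), start=1
        ):
            mark = "*" if state else "."
            fh.write(f"{i:5d} {letter} {mark} {p:5.3f}\n")


# ---------------------------------------------------------------------------
# RSA derivation and RSA/prediction TSVs
# ---------------------------------------------------------------------------

def rsa_from_dssp_acc(
    acc_values,
    sequence: str,
    max_asa_table: MaxAsaTable,
    unit_scale: str = "fraction",
) -> RsaTrack:
    """Normalise DSSP ACC (A^2) to RSA: rsa[i] = acc[i] / maxASA(sequence[i]).

    Values above the ceiling (DSSP ACC occasionally exceeds tabulated maxima)
    are clamped with a warning. Negative ACC is a format error.
    """
    acc = np.asarray(acc_values, dtype=float)
    if acc.shape[0] != len(sequence):
        raise LengthMismatchError(
            f"{acc.shape[0]} ACC values for a sequence of length {len(sequence)}"
        )
    if np.any(acc < 0):
        raise FormatError("negative ACC value")
    denom = np.array([max_asa_table[a] for a in sequence], dtype=float)
    rsa = acc / denom
    if unit_scale == "percent":
        rsa = rsa * 100.0
    ceiling = 1.0 if unit_scale == "fraction" else 100.0
    n_over = int(np.sum(rsa > ceiling))
    if n_over:
        warnings.warn(f"{n_over} RSA value(s) above {ceiling} clamped", stacklevel=2)
        rsa = np.minimum(rsa, ceiling)
    return RsaTrack(rsa, unit_scale=unit_scale)


def read_acc_tsv(path) -> tuple[str, np.ndarray]:
    """Read a minimal DSSP-derived TSV of (position, residue, ACC) columns."""
    seq, acc = [], []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise FormatError(f"{path}:{lineno}: expected 3 tab-separated columns")
        seq.append(parts[1])
        acc.append(float(parts[2]))
    if not seq:
        raise FormatError(f"{path}: empty ACC table")
    return "".join(seq), np.array(acc, dtype=float)


def read_rsa_table(path, unit_scale: str = "fraction") -> tuple[str, str, RsaTrack]:
    """Read a single-chain RSA TSV of (chain_id, position, residue, rsa) rows.

    Rows may arrive out of order; they are sorted by position. Duplicate
    positions or multiple chain ids are format errors. Returns
    (chain_id, sequence, track).
    """
    rows = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 4:
            raise FormatError(f"{path}:{lineno}: expected 4 tab-separated columns")
        rows.append((parts[0], int(parts[1]), parts[2], float(parts[3])))
    if not rows:
        raise FormatError(f"{path}: empty RSA table")
    ids = {r[0] for r in rows}
    if len(ids) != 1:
        raise FormatError(f"{path}: expected one chain id, found {sorted(ids)}")
    rows.sort(key=lambda r: r[1])
    positions = [r[1] for r in rows]
    if len(set(positions)) != len(positions):
        raise FormatError(f"{path}: duplicate positions")
    if positions != list(range(1, len(rows) + 1)):
        raise FormatError(f"{path}: positions are not contiguous from 1")
    chain_id = rows[0][0]
    sequence = "".join(r[2] for r in rows)
    track = RsaTrack(np.array([r[3] for r in rows]), unit_scale=unit_scale)
    return chain_id, sequence, track


def read_chain_dir(path, disorder_threshold: float = 0.5) -> list[ChainRecord]:
    """Load every chain in a fixture directory.

    For each ``<id>.fasta`` the companions ``<id>.pssm``, ``<id>.ss2``,
    ``<id>.diso`` and ``<id>.rsa.tsv`` are attached when present.
    """
    root = Path(path)
    fastas = sorted(root.glob("*.fasta"))
    if not fastas:
        raise FormatError(f"{path}: no .fasta files found")
    chains = []
    for fasta in fastas:
        (chain,) = read_fasta(fasta)
        base = fasta.with_suffix("")
        L = chain.length
        if base.with_suffix(".pssm").exists():
            chain.pssm = read_pssm(base.with_suffix(".pssm"), L)
        if base.with_suffix(".ss2").exists():
            chain.ss3 = read_psipred_ss2(base.with_suffix(".ss2"), L)
        if base.with_suffix(".diso").exists():
            chain.disorder = read_disopred(base.with_suffix(".diso"), L, disorder_threshold)
        rsa_path = root / f"{base.name}.rsa.tsv"
        if rsa_path.exists():
            _, seq, track = read_rsa_table(rsa_path)
            if seq != chain.sequence:
                raise FormatError(f"{rsa_path}: sequence disagrees with {fasta.name}")
            chain.rsa = track
        chains.append(chain)
    return chains


def write_predictions(path, chain_id: str, sequence: str, track: RsaTrack) -> None:
    """Write an RSA/prediction TSV in the same dialect :func:`read_rsa_table` reads."""
    if len(sequence) != len(track):
        raise LengthMismatchError("sequence and RSA track differ in length")
    with open(path, "w") as fh:
        for i, (letter, value) in enumerate(zip(sequence, track.rsa), start=1):
            fh.write(f"{chain_id}\t{i}\t{letter}\t{value:.17g}\n")
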