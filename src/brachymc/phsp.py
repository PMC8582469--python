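"""Phase-space files: generation, binary round trip, pose-transformed replay.

A phase-space (PHSP) file freezes every photon that leaves a seed's outer
surface — type, energy, position on the capture surface (seed local frame,
mm), direction and weight — so any later simulation can replay the seed as a
source without re-modelling its internal geometry.

Binary layout (little endian), version 1:

    offset  size  field
    0       8     magic  b"BRMCPHSP"
    8       2     format version (uint16)
    10      32    seed id (ascii, zero padded)
    42      8     nuclide (ascii, zero padded)
    50      8     primaries consumed (uint64)
    58      8     records stored (uint64)
    66      8     generation rng seed (uint64)
    74      4     CRC32 of the record block (uint32)
    78      2     reserved
    80      -     records, 57 bytes each:
                  type uint8 (0 = photon), energy float64 keV,
                  position float64[3] mm, direction float64[3], weight float64

Only photons are recorded; fluorescence generated inside the seed is not
transported during generation (primary-line photons only), while capsule
attenuation and scatter do shape the recorded energies and directions.
"""

from __future__ import annotations

import struct
import zlib
from dataclasses import dataclass

import numpy as np

from .geometry import Pose, SeedModel

MAGIC = b"BRMCPHSP"
VERSION = 1
HEADER_SIZE = 80
PHOTON = 0

RECORD_DTYPE = np.dtype([
    ("ptype", "<u1"),
    ("energy", "<f8"),
    ("x", "<f8"), ("y", "<f8"), ("z", "<f8"),
    ("ux", "<f8"), ("uy", "<f8"), ("uz", "<f8"),
    ("weight", "<f8"),
])


class PhspFormatError(ValueError):
    pass


class PhspVersionError(PhspFormatError):
    pass


class PhspChecksumError(PhspFormatError):
    pass


class PhspTruncatedError(PhspFormatError):
    pass


@dataclass
class PhspFile:
    seed_id: str
    nuclide: str
    n_primary: int
    rng_seed: int
    records: np.ndarray            # RECORD_DTYPE

    @property
    def n_records(self) -> int:
        return int(self.records.size)

    @property
    def energies(self):
        return self.records["energy"]

    @property
    def positions_mm(self):
        return np.stack([self.records[c] for c in "xyz"], axis=1)

    @property
    def directions(self):
        return np.stack([self.records[c] for c in ("ux", "uy", "uz")], axis=1)

    @property
    def mean_energy(self) -> float:
        return float(np.average(self.energies,
                                weights=self.records["weight"]))

    def validate(self, max_line_kev: float | None = None):
        d = self.directions
        norms = np.linalg.norm(d, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise PhspFormatError("non-unit direction in records")
        if np.any(self.energies <= 0) or np.any(self.records["weight"] <= 0):
            raise PhspFormatError("non-positive energy or weight")
        if max_line_kev is not None and np.any(
                self.energies > max_line_kev + 1e-9):
            raise PhspFormatError("record energy above the source spectrum")

    def info(self) -> dict:
        return {
            "seed_id": self.seed_id, "nuclide": self.nuclide,
            "n_records": self.n_records, "n_primary": self.n_primary,
            "rng_seed": self.rng_seed,
            "mean_energy_keV": self.mean_energy,
            "escape_fraction": self.n_records / max(self.n_primary, 1),
        }


def generate_phsp(seed: SeedModel, n_records: int,
                  rng: np.random.Generator | int,
                  batch_size: int = 200_000,
                  max_attempt_factor: int = 50) -> PhspFile:
    """Generate a PHSP by transporting decay photons out of the seed.

    Emission, capsule attenuation and in-capsule scatter follow the seed
    model; fluorescence is disabled (primary-line photons only).  Exactly
    ``n_records`` records are stored; the header keeps the number of
    primaries actually consumed.
    """
    from .transport import transport_through_seed
    if n_records < 1:
        raise ValueError("n_records must be >= 1")
    rng_seed = int(rng) if isinstance(rng, (int, np.integer)) else None
    if rng_seed is not None:
        rng = np.random.default_rng(rng_seed)
    else:
        rng_seed = 0
    chunks = []
    collected = 0
    consumed = 0
    attempts = 0
    while collected < n_records:
        n_batch = min(batch_size,
                      max(4096, int((n_records - collected) * 2.5)))
        ph = transport_through_seed(seed, n_batch, rng, fluorescence=False,
                                    first_primary_index=consumed)
        consumed += n_batch
        attempts += n_batch
        if ph.n:
            chunks.append(ph)
            collected += ph.n
        if attempts > max_attempt_factor * max(n_records, 1) + 10_000:
            raise RuntimeError(
                f"{seed.seed_id}: generation stalled after {attempts} "
                "primaries (non-emitting model?)")
    order_e = np.concatenate([c.energy_kev for c in chunks])
    order_p = np.concatenate([c.position_mm for c in chunks])
    order_d = np.concatenate([c.direction for c in chunks])
    order_w = np.concatenate([c.weight for c in chunks])
    order_i = np.concatenate([c.primary_index for c in chunks])
    srt = np.argsort(order_i, kind="stable")[:n_records]
    n_primary = int(order_i[srt[-1]]) + 1
    rec = np.zeros(n_records, RECORD_DTYPE)
    rec["ptype"] = PHOTON
    rec["energy"] = order_e[srt]
    rec["x"], rec["y"], rec["z"] = order_p[srt].T
    rec["ux"], rec["uy"], rec["uz"] = order_d[srt].T
    rec["weight"] = order_w[srt]
    out = PhspFile(seed_id=seed.seed_id, nuclide=seed.nuclide,
                   n_primary=n_primary, rng_seed=rng_seed, records=rec)
    out.validate(max_line_kev=seed.spectrum.max_energy)
    return out


def write_phsp(phsp: PhspFile, path) -> None:
    body = phsp.records.tobytes()
    header = struct.pack(
        "<8sH32s8sQQQIH",
        MAGIC, VERSION,
        phsp.seed_id.encode()[:32].ljust(32, b"\0"),
        phsp.nuclide.encode()[:8].ljust(8, b"\0"),
        phsp.n_primary, phsp.n_records, phsp.rng_seed,
        zlib.crc32(body) & 0xFFFFFFFF, 0)
    assert len(header) == HEADER_SIZE
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(body)


def read_phsp(path) -> PhspFile:
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < HEADER_SIZE or raw[:8] != MAGIC:
        raise PhspFormatError("not a PHSP file")
    (magic, version, seed_id, nuclide, n_primary, n_rec, rng_seed,
     checksum, _pad) = struct.unpack("<8sH32s8sQQQIH", raw[:HEADER_SIZE])
    if version != VERSION:
        raise PhspVersionError(f"unsupported PHSP version {version}")
    body = raw[HEADER_SIZE:]
    expected = n_rec * RECORD_DTYPE.itemsize
    if len(body) != expected:
        raise PhspTruncatedError(
            f"body holds {len(body)} bytes, header promises {expected}")
    if zlib.crc32(body) & 0xFFFFFFFF != checksum:
        raise PhspChecksumError("record block checksum mismatch")
    records = np.frombuffer(body, RECORD_DTYPE).copy()
    return PhspFile(seed_id=seed_id.rstrip(b"\0").decode(),
                    nuclide=nuclide.rstrip(b"\0").decode(),
                    n_primary=int(n_primary), rng_seed=int(rng_seed),
                    records=records)


def export_hdf5(phsp: PhspFile, path) -> None:
    """Optional export to an open hierarchical container (same fields)."""
    import h5py
    with h5py.File(path, "w") as h5:
        h5.attrs.update({"seed_id": phsp.seed_id, "nuclide": phsp.nuclide,
                         "n_primary": phsp.n_primary,
                         "rng_seed": phsp.rng_seed, "version": VERSION})
        h5.create_dataset("ptype", data=phsp.records["ptype"])
        h5.create_dataset("energy_keV", data=phsp.energies)
        h5.create_dataset("position_mm", data=phsp.positions_mm)
        h5.create_dataset("direction", data=phsp.directions)
        h5.create_dataset("weight", data=phsp.records["weight"])


def replay_source(phsp: PhspFile, pose: Pose, n: int,
                  rng: np.random.Generator, cyclic: bool = False):
    """Draw records (uniform with replacement, or cyclically) and map them
    into the world frame through ``pose``.

    Returns ``(energy keV, position mm, direction, weight, history index)``.
    """
    if phsp.n_records == 0:
        raise PhspFormatError("cannot replay an empty PHSP")
    if n < 1:
        raise ValueError("n must be >= 1")
    if cyclic:
        idx = np.arange(n) % phsp.n_records
    else:
        idx = rng.integers(0, phsp.n_records, size=n)
    pos = pose.apply_points(phsp.positions_mm[idx])
    dirs = pose.apply_directions(phsp.directions[idx])
    return (phsp.energies[idx].copy(), pos, dirs,
            phsp.records["weight"][idx].copy(),
            np.arange(n, dtype=np.int64))
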