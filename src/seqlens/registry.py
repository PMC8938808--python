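"""Dataset manifests and analysis-ready dataset instances.

A dataset is described by a flat YAML/JSON manifest: conditions, samples and
the concrete files behind them (BAM alignments, normalized BigWig signal
tracks, annotation). A *dataset instance* is a validated selection of those
samples grouped by biological condition — the unit every downstream analysis
operates on. Instances are plain serializable JSON files, so a selection can
be recreated, diffed and shared.
"""

from __future__ import annotations

import datetime
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pydantic
import pysam
import yaml

logger = logging.getLogger(__name__)


class ManifestError(ValueError):
    """Schema or invariant violation in a dataset manifest."""


class SelectionError(KeyError):
    """Unknown condition or sample name in an instance selection."""


class SampleRecord(pydantic.BaseModel):
    """One sequenced sample: its condition and the files that back it.

    ``library_size`` is the number of primary, QC-pass, non-duplicate mapped
    alignment records; when absent it is computed from the BAM on first use
    and cached on the record.
    """

    model_config = pydantic.ConfigDict(extra="forbid", validate_assignment=True)

    sample_id: str
    condition: str
    bam_path: Path | None = None
    bigwig_path: Path | None = None
    counts_path: Path | None = None
    library_size: int | None = pydantic.Field(default=None, gt=0)

    @pydantic.model_validator(mode="after")
    def _at_least_one_source(self) -> "SampleRecord":
        if self.bam_path is None and self.bigwig_path is None:
            raise ValueError(
                f"sample {self.sample_id!r}: at least one of bam_path/"
                "bigwig_path is required"
            )
        return self

    def get_library_size(self) -> int:
        """Library size, computing it from the BAM on first use."""
        if self.library_size is None:
            if self.bam_path is None:
                raise ManifestError(
                    f"sample {self.sample_id!r}: library_size unknown and no "
                    "BAM to compute it from"
                )
            self.library_size = count_primary_reads(self.bam_path)
            logger.info(
                "sample %s: library_size computed from BAM = %d",
                self.sample_id, self.library_size,
            )
        return self.library_size


class DatasetManifest(pydantic.BaseModel):
    """The flat, diffable description of one hosted dataset."""

    model_config = pydantic.ConfigDict(extra="forbid")

    dataset_id: str
    genome_id: str
    annotation_path: Path
    chrom_sizes_path: Path | None = None
    samples: list[SampleRecord]

    @pydantic.model_validator(mode="after")
    def _invariants(self) -> "DatasetManifest":
        seen: set[str] = set()
        for s in self.samples:
            if s.sample_id in seen:
                raise ValueError(f"duplicate sample_id {s.sample_id!r}")
            seen.add(s.sample_id)
        if not self.conditions:
            raise ValueError("manifest must declare at least one condition")
        return self

    @property
    def conditions(self) -> list[str]:
        """Condition names in first-appearance order."""
        return list(dict.fromkeys(s.condition for s in self.samples))

    def sample(self, sample_id: str) -> SampleRecord:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise SelectionError(f"unknown sample {sample_id!r}")

    def samples_of(self, condition: str) -> list[SampleRecord]:
        return [s for s in self.samples if s.condition == condition]


@dataclass
class DatasetInstance:
    """A validated selection of manifest samples grouped by condition."""

    manifest: DatasetManifest
    selected: dict[str, list[str]]
    created_at: str = field(
        default_factory=lambda: datetime.datetime.now(
            datetime.timezone.utc
        ).isoformat()
    )
    manifest_path: Path | None = None

    @property
    def conditions(self) -> list[str]:
        return list(self.selected)

    def samples_of(self, condition: str) -> list[SampleRecord]:
        if condition not in self.selected:
            raise SelectionError(f"condition {condition!r} not in instance")
        return [self.manifest.sample(sid) for sid in self.selected[condition]]

    def all_samples(self) -> list[SampleRecord]:
        """Selected samples in instance order, grouped by condition."""
        return [s for c in self.selected for s in self.samples_of(c)]

    def save(self, path: str | Path) -> None:
        if self.manifest_path is None:
            raise ManifestError(
                "instance has no manifest_path; load the manifest from a file "
                "before saving the instance"
            )
        payload = {
            "manifest": str(self.manifest_path),
            "selected": self.selected,
            "created_at": self.created_at,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def count_primary_reads(bam_path: str | Path) -> int:
    """Primary, QC-pass, non-duplicate mapped records in a BAM."""
    n = 0
    with pysam.AlignmentFile(str(bam_path)) as bam:
        for read in bam.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.is_qcfail or read.is_duplicate:
                continue
            n += 1
    return n


# ---------------------------------------------------------------------------
# load_manifest / create_instance
# ---------------------------------------------------------------------------

def load_manifest(path: str | Path) -> DatasetManifest:
    """Load and validate a YAML or JSON dataset manifest.

    Relative file paths are resolved against the manifest's directory.
    Referenced files are not required to exist at load time; existence is
    checked by :func:`validate_instance`.
    """
    path = Path(path)
    if not path.exists():
        raise ManifestError(f"manifest not found: {path}")
    text = path.read_text()
    try:
        if path.suffix.lower() == ".json":
            raw = json.loads(text)
        else:
            raw = yaml.safe_load(text)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise ManifestError(f"failed to parse manifest {path}: {exc}") from exc
    try:
        manifest = DatasetManifest.model_validate(raw)
    except pydantic.ValidationError as exc:
        raise ManifestError(f"invalid manifest {path}:\n{exc}") from exc

    base = path.parent
    def _resolve(p: Path | None) -> Path | None:
        return None if p is None else (p if p.is_absolute() else base / p)

    manifest.annotation_path = _resolve(manifest.annotation_path)
    manifest.chrom_sizes_path = _resolve(manifest.chrom_sizes_path)
    for s in manifest.samples:
        s.bam_path = _resolve(s.bam_path)
        s.bigwig_path = _resolve(s.bigwig_path)
        s.counts_path = _resolve(s.counts_path)
    return manifest


def create_instance(
    manifest: DatasetManifest,
    selection: dict[str, list[str]] | None = None,
    manifest_path: str | Path | None = None,
) -> DatasetInstance:
    """Create a dataset instance from a manifest.

    ``selection`` maps condition name to the sample ids to keep; omitted
    conditions are excluded, which is how a big dataset is subsetted. With
    ``selection=None`` every sample is selected.
    """
    if selection is None:
        selection = {
            c: [s.sample_id for s in manifest.samples_of(c)]
            for c in manifest.conditions
        }
    if not selection:
        raise SelectionError("selection is empty")
    known = {s.sample_id: s.condition for s in manifest.samples}
    resolved: dict[str, list[str]] = {}
    for cond, sids in selection.items():
        if cond not in manifest.conditions:
            raise SelectionError(f"unknown condition {cond!r}")
        if not sids:
            raise SelectionError(f"condition {cond!r}: empty sample selection")
        for sid in sids:
            if sid not in known:
                raise SelectionError(f"unknown sample {sid!r}")
            if known[sid] != cond:
                raise SelectionError(
                    f"sample {sid!r} belongs to condition {known[sid]!r}, "
                    f"not {cond!r}"
                )
        resolved[cond] = list(sids)
    return DatasetInstance(
        manifest=manifest,
        selected=resolved,
        manifest_path=None if manifest_path is None else Path(manifest_path),
    )


def load_instance(path: str | Path) -> DatasetInstance:
    """Load a serialized instance (JSON) and its manifest."""
    path = Path(path)
    payload = json.loads(path.read_text())
    mpath = Path(payload["manifest"])
    if not mpath.is_absolute():
        mpath = path.parent / mpath
    manifest = load_manifest(mpath)
    inst = create_instance(manifest, payload["selected"], manifest_path=mpath)
    inst.created_at = payload.get("created_at", inst.created_at)
    return inst


# ---------------------------------------------------------------------------
# validate_instance
# ---------------------------------------------------------------------------

@dataclass
class SampleCheck:
    sample_id: str
    resources: dict[str, bool]
    messages: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return all(self.resources.values())


@dataclass
class ValidationReport:
    checks: list[SampleCheck]
    require: frozenset[str]

    @property
    def passed(self) -> bool:
        return all(c.ok for c in self.checks)

    def failures(self) -> list[SampleCheck]:
        return [c for c in self.checks if not c.ok]

    def __str__(self) -> str:
        lines = [f"validation ({'PASS' if self.passed else 'FAIL'}), "
                 f"require={sorted(self.require)}"]
        for c in self.checks:
            status = "ok" if c.ok else "FAIL"
            lines.append(f"  {c.sample_id}: {status} {c.resources}")
            lines.extend(f"    - {m}" for m in c.messages)
        return "\n".join(lines)


_VALID_RESOURCES = frozenset({"bam", "bigwig", "counts"})


def validate_instance(
    instance: DatasetInstance, require: set[str] | frozenset[str] = frozenset({"bam"})
) -> ValidationReport:
    """Check, per selected sample, that every required resource exists and
    opens. Problems are reported, never raised; the report passes only if
    every required resource is usable. Library sizes are filled in (and
    cached) for BAM-backed samples.
    """
    require = frozenset(require)
    unknown = require - _VALID_RESOURCES
    if unknown:
        raise ValueError(f"unknown resources {sorted(unknown)}; "
                         f"choose from {sorted(_VALID_RESOURCES)}")
    checks: list[SampleCheck] = []
    for sample in instance.all_samples():
        resources: dict[str, bool] = {}
        messages: list[str] = []
        if "bam" in require:
            resources["bam"] = _check_bam(sample, messages)
        if "bigwig" in require:
            resources["bigwig"] = _check_bigwig(sample, messages)
        if "counts" in require:
            if sample.counts_path is None:
                resources["counts"] = False
                messages.append(
                    "no counts table configured; add counts_path to the "
                    "manifest or quantify from BAM"
                )
            elif not Path(sample.counts_path).exists():
                resources["counts"] = False
                messages.append(f"counts table missing: {sample.counts_path}")
            else:
                resources["counts"] = True
        checks.append(SampleCheck(sample.sample_id, resources, messages))
    return ValidationReport(checks=checks, require=require)


def _check_bam(sample: SampleRecord, messages: list[str]) -> bool:
    if sample.bam_path is None:
        messages.append("no BAM configured (this analysis requires BAM files)")
        return False
    p = Path(sample.bam_path)
    if not p.exists():
        messages.append(f"BAM missing: {p}")
        return False
    try:
        with pysam.AlignmentFile(str(p)) as bam:
            if not bam.has_index():
                messages.append(f"BAM not indexed: {p} (run samtools index)")
                return False
    except (OSError, ValueError) as exc:
        messages.append(f"BAM unreadable: {p}: {exc}")
        return False
    try:
        sample.get_library_size()
    except ManifestError as exc:
        messages.append(str(exc))
    return True


def _check_bigwig(sample: SampleRecord, messages: list[str]) -> bool:
    if sample.bigwig_path is None:
        messages.append("no BigWig configured")
        return False
    p = Path(sample.bigwig_path)
    if not p.exists():
        messages.append(f"BigWig missing: {p}")
        return False
    try:
        import pyBigWig

        bw = pyBigWig.open(str(p))
        bw.close()
    except (OSError, RuntimeError) as exc:
        messages.append(f"BigWig unreadable: {p}: {exc}")
        return False
    return True
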