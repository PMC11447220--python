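"""Biallelic TP53 loss-of-function genotype labeling.

A sample is labeled ``dual_loss`` when it carries two TP53 coding mutations,
or a single coding mutation together with copy-number loss — the
high-confidence biallelic loss-of-function genotype used as the training
label.  MDM2 alterations (which degrade wild-type p53 and mimic genomic TP53
loss) can optionally count toward the ``tp53_loss`` label.

Copy-number loss is called under a named threshold scheme because public
datasets discretize differently: GISTIC <= -1, GISTIC < -1 (i.e. only deep
deletions), or log2 ratio < -1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import ConfigurationError, ValidationError

# MAF-standard Variant_Classification vocabulary -> (coding?, category).
# The vocabulary is a module-level mapping so other dialects can be declared
# by passing a custom table.
VARIANT_VOCABULARY: dict[str, tuple[bool, str]] = {
    "Missense_Mutation": (True, "missense"),
    "Nonsense_Mutation": (True, "nonsense"),
    "Frame_Shift_Del": (True, "frameshift"),
    "Frame_Shift_Ins": (True, "frameshift"),
    "In_Frame_Del": (True, "inframe_indel"),
    "In_Frame_Ins": (True, "inframe_indel"),
    "Splice_Site": (True, "splice"),
    "Nonstop_Mutation": (True, "other_coding"),
    "Translation_Start_Site": (True, "other_coding"),
    "Silent": (False, "non_coding"),
    "Splice_Region": (False, "non_coding"),
    "Intron": (False, "non_coding"),
    "3'UTR": (False, "non_coding"),
    "5'UTR": (False, "non_coding"),
    "3'Flank": (False, "non_coding"),
    "5'Flank": (False, "non_coding"),
    "RNA": (False, "non_coding"),
    "IGR": (False, "non_coding"),
    "Targeted_Region": (False, "non_coding"),
}

CN_LOSS_RULES = ("gistic_le_minus1", "gistic_lt_minus1", "log2_lt_minus1")

#: GISTIC discrete value taken as amplification; log2 ratio > 1 likewise
MDM2_AMP_GISTIC = 2
MDM2_AMP_LOG2 = 1.0


def classify_variant(classification: str,
                     vocabulary: dict[str, tuple[bool, str]] | None = None
                     ) -> tuple[bool, str]:
    """Map a Variant_Classification string to (coding flag, mutation category).

    Raises
    ------
    ValidationError
        If the string is not in the declared vocabulary.
    """
    vocab = VARIANT_VOCABULARY if vocabulary is None else vocabulary
    try:
        return vocab[classification]
    except KeyError:
        raise ValidationError(
            f"unknown variant classification {classification!r}; "
            f"declared vocabulary: {sorted(vocab)}") from None


@dataclass(frozen=True)
class ThresholdScheme:
    """Named copy-number loss rule for one dataset's discretization."""

    name: str
    cn_loss_rule: str

    def __post_init__(self) -> None:
        if self.cn_loss_rule not in CN_LOSS_RULES:
            raise ConfigurationError(
                f"unknown cn_loss_rule {self.cn_loss_rule!r}; expected one of {CN_LOSS_RULES}")

    @property
    def value_kind(self) -> str:
        return "log2_ratio" if self.cn_loss_rule == "log2_lt_minus1" else "gistic_discrete"

    def is_loss(self, value: float) -> bool:
        if self.cn_loss_rule == "gistic_le_minus1":
            return value <= -1
        if self.cn_loss_rule == "gistic_lt_minus1":
            return value < -1
        return value < -1.0  # log2_lt_minus1


#: the three dataset conventions
TCGA_SCHEME = ThresholdScheme("tcga", "gistic_le_minus1")
GDSC_SCHEME = ThresholdScheme("gdsc", "gistic_lt_minus1")
CCLE_SCHEME = ThresholdScheme("ccle", "log2_lt_minus1")
SCHEMES = {s.name: s for s in (TCGA_SCHEME, GDSC_SCHEME, CCLE_SCHEME)}


@dataclass
class AlterationTables:
    """Mutation records plus gene-level copy-number calls.

    ``mutations`` columns: sample, gene, variant_classification and an
    optional protein_change used for deduplication.  ``copy_number`` columns:
    sample, gene, value; ``value_kind`` declares the discretization.
    """

    mutations: pd.DataFrame
    copy_number: pd.DataFrame
    value_kind: str = "gistic_discrete"

    MUT_COLS = ("sample", "gene", "variant_classification")
    CN_COLS = ("sample", "gene", "value")

    def __post_init__(self) -> None:
        for col in self.MUT_COLS:
            if col not in self.mutations.columns:
                raise ValidationError(f"mutation table missing column {col!r}")
        for col in self.CN_COLS:
            if col not in self.copy_number.columns:
                raise ValidationError(f"copy-number table missing column {col!r}")
        if self.value_kind not in ("gistic_discrete", "log2_ratio"):
            raise ConfigurationError(f"unknown value_kind {self.value_kind!r}")
        dup = self.copy_number.duplicated(subset=["sample", "gene"], keep=False)
        if dup.any():
            grp = self.copy_number[dup].groupby(["sample", "gene"])["value"].nunique()
            conflicts = grp[grp > 1]
            if len(conflicts):
                raise ValidationError(
                    f"conflicting copy-number records for (sample, gene): "
                    f"{list(conflicts.index[:5])}")
            # identical duplicates: keep one
            object.__setattr__(self, "copy_number",
                               self.copy_number.drop_duplicates(subset=["sample", "gene"]))

    # -- I/O (MAF-like mutation TSV; gene x sample CN TSV) ----------------
    @classmethod
    def from_tsv(cls, mutations_path: str | Path, copy_number_path: str | Path,
                 value_kind: str = "gistic_discrete") -> "AlterationTables":
        maf = pd.read_csv(mutations_path, sep="\t")
        rename = {"Tumor_Sample_Barcode": "sample", "Hugo_Symbol": "gene",
                  "Variant_Classification": "variant_classification",
                  "Protein_Change": "protein_change", "HGVSp_Short": "protein_change"}
        maf = maf.rename(columns={k: v for k, v in rename.items() if k in maf.columns})
        cn_wide = pd.read_csv(copy_number_path, sep="\t", index_col=0)
        cn = cn_wide.stack().rename("value").reset_index()
        cn.columns = ["gene", "sample", "value"]
        return cls(mutations=maf, copy_number=cn[["sample", "gene", "value"]],
                   value_kind=value_kind)


def call_tp53_loss(tables: AlterationTables, scheme: ThresholdScheme,
                   mdm2_policy: str = "any",
                   vocabulary: dict[str, tuple[bool, str]] | None = None) -> pd.DataFrame:
    """Label every sample's TP53 genotype class.

    Rules: ``dual_loss`` iff (>= 2 distinct TP53 coding mutations) or
    (>= 1 coding mutation and TP53 copy-number loss under the scheme);
    ``single_alteration`` for exactly one of those events; ``none``
    otherwise.  ``tp53_loss`` (the training label) is true for ``dual_loss``
    or, depending on ``mdm2_policy``, for MDM2-altered samples.

    Parameters
    ----------
    mdm2_policy
        ``"any"`` — MDM2 amplification or any MDM2 coding mutation sets
        ``mdm2_altered`` and suffices for ``tp53_loss``;
        ``"amplification_only"`` — only amplification counts;
        ``"ignore"`` — MDM2 is not considered.

    Returns
    -------
    DataFrame indexed by sample with columns
    ``tp53_coding_mutation_count``, ``tp53_cn_loss``, ``mdm2_altered``,
    ``allele_class``, ``tp53_loss``.
    """
    if mdm2_policy not in ("any", "amplification_only", "ignore"):
        raise ConfigurationError(f"unknown mdm2_policy {mdm2_policy!r}")
    if scheme.value_kind != tables.value_kind:
        raise ConfigurationError(
            f"scheme {scheme.name!r} expects {scheme.value_kind}, "
            f"copy-number table declares {tables.value_kind}")

    mut = tables.mutations.copy()
    dedup_cols = [c for c in ("sample", "gene", "variant_classification", "protein_change")
                  if c in mut.columns]
    mut = mut.drop_duplicates(subset=dedup_cols)
    if len(mut):
        coding = mut["variant_classification"].map(
            lambda c: classify_variant(c, vocabulary)[0])
    else:
        coding = pd.Series(dtype=bool)

    samples = pd.Index(sorted(set(tables.mutations["sample"]).union(
        tables.copy_number["sample"])), name="sample")

    tp53_mut = mut[(mut["gene"] == "TP53") & coding]
    mut_count = tp53_mut.groupby("sample").size().reindex(samples, fill_value=0)

    cn = tables.copy_number
    tp53_cn = cn[cn["gene"] == "TP53"].set_index("sample")["value"]
    cn_loss = tp53_cn.map(scheme.is_loss).reindex(samples, fill_value=False).astype(bool)

    mdm2_cn = cn[cn["gene"] == "MDM2"].set_index("sample")["value"]
    if tables.value_kind == "gistic_discrete":
        mdm2_amp = mdm2_cn.ge(MDM2_AMP_GISTIC)
    else:
        mdm2_amp = mdm2_cn.gt(MDM2_AMP_LOG2)
    mdm2_amp = mdm2_amp.reindex(samples, fill_value=False).astype(bool)
    mdm2_mut_samples = set(mut[(mut["gene"] == "MDM2") & coding]["sample"])
    if mdm2_policy == "ignore":
        mdm2_altered = pd.Series(False, index=samples)
    elif mdm2_policy == "amplification_only":
        mdm2_altered = mdm2_amp
    else:
        mdm2_altered = mdm2_amp | samples.isin(mdm2_mut_samples)

    dual = (mut_count >= 2) | ((mut_count >= 1) & cn_loss)
    single = ~dual & ((mut_count == 1) | cn_loss)
    allele_class = pd.Series("none", index=samples)
    allele_class[single] = "single_alteration"
    allele_class[dual] = "dual_loss"
    tp53_loss = dual | mdm2_altered

    return pd.DataFrame({
        "tp53_coding_mutation_count": mut_count.astype(int),
        "tp53_cn_loss": cn_loss,
        "mdm2_altered": mdm2_altered.astype(bool),
        "allele_class": allele_class,
        "tp53_loss": tp53_loss.astype(bool),
    })


def write_labels(labels: pd.DataFrame, path: str | Path) -> None:
    out = labels.reset_index().rename(columns={"index": "sample"})
    out.to_csv(path, sep="\t", index=False)
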