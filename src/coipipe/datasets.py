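"""Curated dual-database conflict cases for validating reconciliation.

A set of real-world conflicts observed when identifying Singapore
fish-larvae COI mOTUs against both the GenBank nt database and a curated
local database: each case records the two databases' top hits (species
name and percent identity), the lineages involved, and the accepted final
identification. Five cases carry curated overrides (photograph-verified
vouchers, nomenclatural revisions, a propagated GenBank misidentification)
and one is resolved mechanically by flagging a single misidentified
reference accession against a concordant majority. The remainder resolve
conservatively to the lowest common rank.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from coipipe.taxassign import Hit


def _lineage(order: str, family: str, genus: str, species: str) -> dict[str, str]:
    return {
        "kingdom": "Animalia", "phylum": "Chordata", "class": "Actinopterygii",
        "order": order, "family": family, "genus": genus, "species": species,
    }


def _hit(acc: str, ident: float, order: str, family: str, genus: str,
         species: str) -> Hit:
    return Hit(acc, ident, _lineage(order, family, genus, species))


@dataclass
class ConflictCase:
    motu: str
    hits_nt: list[Hit]
    hits_local: list[Hit]
    expected_final: str
    expected_rank: str
    expected_provenance: str
    note: str = ""


def curated_overrides() -> dict[frozenset[str], tuple[str, str]]:
    """Curated resolutions for conflicts that LCR alone would over-collapse.

    Keys are unordered name pairs; values (final name, rank). The
    Sphyraena pair is also resolvable mechanically by outlier flagging
    when the full nt hit list is available; the override is kept for runs
    where only top hits are recorded.
    """
    rows = [
        ("Apogon sp.", "Ostorhinchus cavitensis", "Ostorhinchus cavitensis", "species"),
        ("Sphyraena putnamae", "Sphyraena jello", "Sphyraena jello", "species"),
        ("Scolopsis vosmeri", "Scolopsis japonicus", "Scolopsis japonicus", "species"),
        ("Amblyeleotris macronema", "Amblyeleotris gymnocephala",
         "Amblyeleotris gymnocephala", "species"),
        ("Cryptocentrus leptocephalus", "Cryptocentrus melanopus",
         "Cryptocentrus melanopus", "species"),
        ("Sparus aurata", "Omobranchus ferox", "Omobranchus ferox", "species"),
    ]
    return {frozenset((a, b)): (final, rank) for a, b, final, rank in rows}


def conflict_cases() -> list[ConflictCase]:
    """The 18 recorded dual-database conflicts with their accepted finals."""
    leio = ("Acanthuriformes", "Leiognathidae")
    apo = ("Kurtiformes", "Apogonidae")
    gobi = ("Gobiiformes", "Gobiidae")
    amba = ("Ovalentaria", "Ambassidae")

    def c(motu, nt, local, final, rank, prov, note=""):
        return ConflictCase(motu, nt, local, final, rank, prov, note)

    return [
        c("Cluster3325",
          [_hit("NT3325", 100.0, *leio, "Photopectoralis", "Photopectoralis bindus")],
          [_hit("LC3325", 100.0, *leio, "Nuchequula", "Nuchequula sp1")],
          "Leiognathidae sp.", "family", "conservative", "both genera valid"),
        c("Cluster5100",
          [_hit("NT5100", 100.0, "Tetraodontiformes", "Monacanthidae",
                "Paramonacanthus", "Paramonacanthus sp.")],
          [_hit("LC5100", 100.0, "Tetraodontiformes", "Monacanthidae",
                "Monacanthus", "Monacanthus sp1")],
          "Monacanthidae sp.", "family", "conservative", "both genera valid"),
        c("Cluster3020",
          [_hit("NT3020", 99.2, *apo, "Lepidamia", "Lepidamia kalosoma")],
          [_hit("LC3020", 100.0, *apo, "Apogonichthyoides", "Apogonichthyoides taeniatus")],
          "Apogonidae sp.", "family", "conservative", "both genera valid"),
        c("Cluster3041",
          [_hit("NT3041", 100.0, *leio, "Eubleekeria", "Eubleekeria jonesi")],
          [_hit("LC3041", 100.0, *leio, "Leiognathus", "Leiognathus equula")],
          "Leiognathidae sp.", "family", "conservative", "both species valid"),
        c("Cluster3107",
          [_hit("NT3107", 100.0, *apo, "Apogon", "Apogon sp.")],
          [_hit("LC3107", 100.0, *apo, "Ostorhinchus", "Ostorhinchus cavitensis")],
          "Ostorhinchus cavitensis", "species", "revised",
          "photograph of matched voucher"),
        c("Cluster3745",
          [_hit("KP856819", 100.0, "Istiophoriformes", "Sphyraenidae",
                "Sphyraena", "Sphyraena putnamae"),
           _hit("NT3745b", 99.8, "Istiophoriformes", "Sphyraenidae",
                "Sphyraena", "Sphyraena jello"),
           _hit("NT3745c", 99.7, "Istiophoriformes", "Sphyraenidae",
                "Sphyraena", "Sphyraena jello")],
          [_hit("LC3745", 100.0, "Istiophoriformes", "Sphyraenidae",
                "Sphyraena", "Sphyraena jello")],
          "Sphyraena jello", "species", "nt",
          "single misidentified accession outvoted by majority"),
        c("Cluster4477",
          [_hit("NT4477", 100.0, *amba, "Ambassis", "Ambassis nalua")],
          [_hit("LC4477", 100.0, *amba, "Ambassis", "Ambassis kopsii")],
          "Ambassis sp.", "genus", "conservative", "both species valid"),
        c("Cluster4491",
          [_hit("NT4491", 99.8, *leio, "Deveximentum", "Deveximentum indicium")],
          [_hit("LC4491", 99.8, *leio, "Deveximentum", "Deveximentum hanedai")],
          "Deveximentum sp.", "genus", "conservative", "both species valid"),
        c("Cluster4624",
          [_hit("NT4624", 99.8, *amba, "Ambassis", "Ambassis dussumieri")],
          [_hit("LC4624", 99.8, *amba, "Ambassis", "Ambassis vachellii")],
          "Ambassis sp.", "genus", "conservative", "both species valid"),
        c("Cluster4631",
          [_hit("KY315395", 100.0, "Spariformes", "Nemipteridae",
                "Scolopsis", "Scolopsis vosmeri")],
          [_hit("LC4631", 100.0, "Spariformes", "Nemipteridae",
                "Scolopsis", "Scolopsis japonicus")],
          "Scolopsis japonicus", "species", "revised",
          "species complex recently revised"),
        c("Cluster5007",
          [_hit("NT5007", 100.0, "Carangiformes", "Carangidae", "Alepes", "Alepes vari")],
          [_hit("LC5007", 100.0, "Carangiformes", "Carangidae", "Alepes", "Alepes djedaba")],
          "Alepes sp.", "genus", "conservative", "both species valid"),
        c("Cluster5156",
          [_hit("NT5156", 99.3, *gobi, "Amblyeleotris", "Amblyeleotris macronema")],
          [_hit("MK777316", 99.7, *gobi, "Amblyeleotris", "Amblyeleotris gymnocephala")],
          "Amblyeleotris gymnocephala", "species", "revised",
          "photograph of matched voucher"),
        c("Cluster5191",
          [_hit("NT5191", 99.8, *amba, "Ambassis", "Ambassis vachellii")],
          [_hit("LC5191", 99.8, *amba, "Ambassis", "Ambassis interrupta")],
          "Ambassis sp.", "genus", "conservative", "both species valid"),
        c("Cluster5216",
          [_hit("NT5216", 100.0, *apo, "Taeniamia", "Taeniamia kagoshimanus")],
          [_hit("LC5216", 99.8, *apo, "Taeniamia", "Taeniamia fucata")],
          "Taeniamia sp.", "genus", "conservative", "both species valid"),
        c("Cluster5221",
          [_hit("NT5221", 100.0, *gobi, "Cryptocentrus", "Cryptocentrus leptocephalus")],
          [_hit("LC5221", 100.0, *gobi, "Cryptocentrus", "Cryptocentrus melanopus")],
          "Cryptocentrus melanopus", "species", "revised", "nomenclature clarified"),
        c("Singleton1465",
          [_hit("NT1465", 98.8, *gobi, "Cryptocentrus", "Cryptocentrus cebuanus")],
          [_hit("LC1465", 99.1, *gobi, "Cryptocentrus", "Cryptocentrus pavoninoides")],
          "Cryptocentrus sp.", "genus", "conservative", "both species valid"),
        c("Cluster5208",
          [_hit("NT5208", 99.8, "Lutjaniformes", "Haemulidae",
                "Pomadasys", "Pomadasys hasta")],
          [_hit("LC5208", 99.8, "Lutjaniformes", "Haemulidae",
                "Pomadasys", "Pomadasys kaakan")],
          "Pomadasys sp.", "genus", "conservative", "both names valid"),
        c("Cluster5177",
          [_hit("OK012057", 99.8, "Spariformes", "Sparidae", "Sparus", "Sparus aurata")],
          [_hit("MG210400", 99.4, "Blenniiformes", "Blenniidae",
                "Omobranchus", "Omobranchus ferox")],
          "Omobranchus ferox", "species", "revised",
          "propagated misidentification in nt"),
    ]


@dataclass
class OutlierCase:
    hits: list[Hit]
    expected_species: str
    expected_flagged: list[str] = field(default_factory=list)


def outlier_reference_case() -> OutlierCase:
    """A lone >=98% hit to the wrong species against a concordant majority.

    Pattern of a single misidentified GenBank record: the top hit names a
    species implausible for the region while every other >=98% accession
    agrees on another species; the majority wins and the singleton
    accession is flagged.
    """
    gobi = ("Gobiiformes", "Gobiidae")
    hits = [
        _hit("AP012957", 99.2, "Ateleopodiformes", "Ateleopodidae",
             "Guentherus", "Guentherus altivela"),
        _hit("NTPB0001", 99.0, *gobi, "Psammogobius", "Psammogobius biocellatus"),
        _hit("NTPB0002", 98.9, *gobi, "Psammogobius", "Psammogobius biocellatus"),
        _hit("NTPB0003", 98.5, *gobi, "Psammogobius", "Psammogobius biocellatus"),
    ]
    return OutlierCase(hits, "Psammogobius biocellatus", ["AP012957"])
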