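"""Bundled reporter-country alias table (ISO 3166 alpha-2).

FAERS/LAERS demographic files carry the reporting country either as an
alpha-2 code, as a full English name, or as free text.  The alias table
below maps the common spellings seen in the extracts (and every country
printed in the database's top-20 reporter list) to alpha-2 codes.  Lookups
are case-insensitive; anything unmatched normalizes to null and is tallied.
"""

from __future__ import annotations

# alias (uppercase) -> ISO 3166 alpha-2
COUNTRY_ALIASES: dict[str, str] = {
    # codes map to themselves
    **{c: c for c in (
        "US", "GB", "JP", "CA", "FR", "DE", "IT", "BR", "ES", "AU",
        "NL", "CN", "CH", "SE", "IN", "CO", "TR", "BE", "AR", "PL",
        "MX", "KR", "DK", "NO", "FI", "IE", "PT", "AT", "GR", "IL",
        "ZA", "RU", "NZ", "TH", "SG", "MY", "PH", "SA", "AE", "CZ",
    )},
    "USA": "US",
    "UNITED STATES": "US",
    "UNITED STATES OF AMERICA": "US",
    "UK": "GB",
    "UNITED KINGDOM": "GB",
    "GREAT BRITAIN": "GB",
    "JAPAN": "JP",
    "CANADA": "CA",
    "FRANCE": "FR",
    "GERMANY": "DE",
    "ITALY": "IT",
    "BRAZIL": "BR",
    "SPAIN": "ES",
    "AUSTRALIA": "AU",
    "NETHERLANDS": "NL",
    "THE NETHERLANDS": "NL",
    "CHINA": "CN",
    "SWITZERLAND": "CH",
    "SWEDEN": "SE",
    "INDIA": "IN",
    "COLOMBIA": "CO",
    "TURKEY": "TR",
    "BELGIUM": "BE",
    "ARGENTINA": "AR",
    "POLAND": "PL",
    "MEXICO": "MX",
    "KOREA, REPUBLIC OF": "KR",
    "SOUTH KOREA": "KR",
    "DENMARK": "DK",
    "NORWAY": "NO",
    "FINLAND": "FI",
    "IRELAND": "IE",
    "PORTUGAL": "PT",
    "AUSTRIA": "AT",
    "GREECE": "GR",
    "ISRAEL": "IL",
    "SOUTH AFRICA": "ZA",
    "RUSSIAN FEDERATION": "RU",
    "RUSSIA": "RU",
    "NEW ZEALAND": "NZ",
    "THAILAND": "TH",
    "SINGAPORE": "SG",
    "MALAYSIA": "MY",
    "PHILIPPINES": "PH",
    "SAUDI ARABIA": "SA",
    "UNITED ARAB EMIRATES": "AE",
    "CZECH REPUBLIC": "CZ",
}
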