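"""Cross-link compounds with PubChem CIDs.

Runs against an injected mock transport so the example works offline; drop
the ``transport=`` argument to query the live PUG REST gateway.
"""

import json

from molscreen import PubChemClient, parse_smiles

def mock_transport(url):
    # the live gateway answers /compound/inchikey/<key>/cids/JSON like this
    return 200, json.dumps({"IdentifierList": {"CID": [702]}})

client = PubChemClient(transport=mock_transport, rate_limit_per_s=0)
ethanol = parse_smiles("CCO ethanol", auto_name="CMPD1")
link = client.lookup_identical(ethanol)
print(f"{link.compound_id}: CID={link.cid} (key {link.query_key})")
print(client.link_table([link]))
# CID 702 is the mock's configured answer; a lookup with no match yields an
# absent CID, and offline mode raises immediately without touching the net.
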