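(((nine_banded_armadillo:45,southern_three_banded_armadillo:45)Cingulata:23,(hoffmanns_two_toed_sloth:58,(southern_tamandua:38,giant_anteater:38)Vermilingua:20)Pilosa:10)Xenarthra:28,((rock_hyrax:62,((african_elephant:8,asian_elephant:8)Elephantidae:47,(west_indian_manatee:30,dugong:30)Sirenia:25)Tethytheria:7)Paenungulata:18,(aardvark:75,((cape_elephant_shrew:30,four_toed_sengi:30)Macroscelidea:40,(cape_golden_mole:65,(lesser_hedgehog_tenrec:45,(talazacs_shrew_tenrec:25,large_eared_tenrec:25)ShrewTenrecs:20)Tenrecidae:20)Tenrecoidea:5)Afroinsectivora:5)Afroinsectiphilia:5)Afrotheria:16)Atlantogenata;
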