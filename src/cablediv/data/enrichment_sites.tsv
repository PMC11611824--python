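site_id	location_name	latitude	longitude	habitat	salinity	water_depth_m	sulfide_class
ME2	Magazzolo Estuary, Sicily, Italy	37.4276	13.2509	River bank in estuary. Fine, gray, non-sulfidic sediment	2	0.5	low
ME3	Magazzolo Estuary, Sicily, Italy	37.4287	13.2506	River bank in estuary. Fine, light gray, non-sulfidic sediment	3	0.5	low
ME20	Magazzolo Estuary, Sicily, Italy	37.4274	13.2492	Isolated lagoon next to estuary, dark gray color, non-sulfidic	20	0.5	low
ED10	Ebro Delta, Spain	40.6364	0.7473	Intertidal salt marsh. Sediment with interspersed black and brown layers	10	0.5	high
ED33	Ebro Delta, Spain	40.6401	0.7399	Intertidal salt marsh. Dark-gray colored, sandy sediment	33	0.5	low
BCZ130	Belgian Coastal Zone, North Sea	51.2688	2.9032	Subtidal marine sediment. Cohesive clay and mud. No bioturbation	30	10	low
BCZ700	Belgian Coastal Zone, North Sea	51.3687	3.2210	Subtidal marine sediment. Cohesive gray mud. Brittle stars	30	10	low
BCZOH	Belgian Coastal Zone, Ostend harbor, North Sea	51.2333	2.9261	Subtidal marine harbor sediment. Sulfidic black mud. No bioturbation	34	13	high
RSM30	Rattekaai Salt Marsh, The Netherlands	51.2621	4.1011	Intertidal creek bed of salt marsh. Black, sulfidic and fine-grained sediment. No bioturbation	30	0.5	high
YR17	Yarra River, Melbourne, Australia	-37.8338	145.0258	Periodically hypoxic estuary site, high seasonal salinity fluctuations. Fine-grained, black, sulfidic sediment	17	2	high
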