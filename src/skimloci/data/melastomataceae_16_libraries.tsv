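species	reads	n_loci	total_bp	coverage_median	coverage_sd	depth_median	depth_sd
Allomaieta_villosa	22583550	682	1486675	0.72	0.14	5	10.28
Bertolonia_acuminata	18820316	682	1433836	0.61	0.13	3	6.04
Blakea_schlimii	6272448	682	1473735	0.60	0.16	3	5.37
Eriocnema_fulva	2369052	614	953093	0.20	0.09	1	1.92
Graffenrieda_moritziana	18255622	683	1646960	0.74	0.13	5	16.22
Henriettea_barkeri	3904930	621	993742	0.25	0.11	1	4.76
Merianthera_pulchra	7262788	571	792362	0.23	0.14	1	3.11
Miconia_dodecandra	14915062	683	1820433	0.76	0.11	4	11.04
Nepsera_aquatica	14750648	682	1034413	0.47	0.17	3	16.74
Opisthocentra_clidemioides	6985796	676	1159469	0.39	0.13	2	3.52
Pterogastra_divaricata	8998186	659	874845	0.34	0.15	2	6.66
Rhexia_virginica	12157014	674	967659	0.38	0.15	2	17.31
Rhynchanthera_bracteata	22213604	528	596533	0.21	0.11	2	10.62
Salpinga_maranoniensis	14197808	478	699934	0.19	0.11	1	15.92
Tibouchina_longifolia	9425454	682	994943	0.42	0.16	3	7.20
Triolena_amazonica	6664094	286	508254	0.14	0.07	1	3.86
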