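promoter	sequence	location	predicted_by
PeMADS2	CCCTAAATGG	-214	consensus
PeMADS2	CCATTCTAGG	-248	consensus
PeMADS2	CTTTAAATGG	-318	consensus
PeMADS2	CTATATTAAG	-750	place
PeMADS2	CATAATTTTG	-1254	place
PeMADS2	CCAAAATTTG	-1548	consensus
PeMADS2	CTAATTTTAG	-1891	place
PeMADS2	CAAAATTTAG	-2236	place
PeMADS2	CATATTAAAG	-2586	place
PeMADS3	CAAAAAAAAG	-443	place
PeMADS3	CTTTTATAAG	-1097	place
PeMADS4	CTTATAAAAG	-65	place
PeMADS4	CTATTATAGG	-434	consensus
PeMADS4	CATATTATAG	-559	place
PeMADS4	CATATTTTGG	-1231	consensus
PeMADS4	CCTATGTAGG	-1912	consensus
PeMADS4	CATATATTAG	-2523	place
PeMADS4	CTTTTTTATG	-2656	place
PeMADS4	CAAAATTTTG	-2980	place
PeMADS4	CAAAATTTTG	-3258	place
PeMADS5	GCTTAATTGG	-175	consensus
PeMADS5	TCAAAATTGG	-738	consensus
PeMADS5	CATAAATATG	-862	place
PeMADS5	CTTTATATTG	-1041	place
PeMADS5	CGATTTAAGG	-1263	consensus
PeMADS6	CCAAATTTGA	-678	consensus
PeMADS6	CAAATTTAAG	-774	place
PeMADS6	GCAAAATAGG	-881	consensus
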