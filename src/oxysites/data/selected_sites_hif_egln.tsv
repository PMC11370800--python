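# Published census of codon positions under positive selection in ray-finned
# fish HIFA and EGLN gene families (episodic: MEME; pervasive: FEL), 1-based
# positions in each family's multiple sequence alignment.
# busted_er values are SYNTHETIC indicator magnitudes (2.5 / 1.0): the source
# publication reports only whether each site's BUSTED evidence ratio exceeded
# 2, not its value. meme_p values were not reported and are left empty.
gene_family	codon	meme_p	busted_er	source
HIF1A	97		2.5	episodic
HIF1A	140		2.5	episodic
HIF1A	142		2.5	episodic
HIF1A	183		2.5	episodic
HIF1A	274		2.5	episodic
HIF1A	295		2.5	episodic
HIF1A	315		2.5	episodic
HIF1A	354		1.0	episodic
HIF1A	469		2.5	episodic
HIF1A	483		2.5	episodic
HIF1A	524		1.0	episodic
HIF1A	629		2.5	episodic
HIF1A	630		1.0	episodic
HIF1A	642		2.5	episodic
HIF1A	656		2.5	episodic
HIF1A	660		2.5	episodic
HIF1A	735		2.5	episodic
HIF1A	805		2.5	episodic
HIF1A	810		2.5	episodic
HIF1A	872		2.5	episodic
HIF1A	883		2.5	episodic
HIF1A	894		2.5	episodic
HIF1A	897		2.5	episodic
HIF1A	905		2.5	episodic
HIF1A	921		2.5	episodic
HIF1A	923		2.5	episodic
HIF1A	956		2.5	episodic
HIF1A	976		2.5	episodic
HIF2A	109		1.0	episodic
HIF2A	156		1.0	episodic
HIF2A	199		1.0	episodic
HIF2A	200		2.5	episodic
HIF2A	201		2.5	episodic
HIF2A	204		2.5	episodic
HIF2A	268		1.0	episodic
HIF2A	281		2.5	episodic
HIF2A	285		1.0	episodic
HIF2A	288		2.5	episodic
HIF2A	545		2.5	episodic
HIF2A	547		2.5	episodic
HIF2A	611		2.5	episodic
HIF2A	613		2.5	episodic
HIF2A	634		2.5	episodic
HIF2A	651		2.5	episodic
HIF2A	681		2.5	episodic
HIF2A	683		2.5	episodic
HIF2A	684		2.5	episodic
HIF2A	686		2.5	episodic
HIF2A	707		2.5	episodic
HIF2A	708		2.5	episodic
HIF2A	712		2.5	episodic
HIF2A	715		2.5	episodic
HIF2A	717		2.5	episodic
HIF2A	722		2.5	episodic
HIF2A	724		2.5	episodic
HIF2A	727		1.0	episodic
HIF2A	731		2.5	episodic
HIF2A	750		1.0	episodic
HIF2A	761		2.5	episodic
HIF2A	773		2.5	episodic
HIF2A	786		2.5	episodic
HIF2A	800		2.5	episodic
HIF2A	816		2.5	episodic
HIF2A	887		2.5	episodic
HIF2A	888		1.0	episodic
HIF2A	912		2.5	episodic
HIF2A	929		2.5	episodic
HIF2A	953		1.0	episodic
HIF2A	1009		1.0	episodic
HIF2A	1079		2.5	episodic
HIF2A	1085		2.5	episodic
HIF2A	1088		2.5	episodic
HIF2A	1090		2.5	episodic
HIF2A	1107		1.0	episodic
HIF2A	1118		1.0	episodic
HIF2A	1121		2.5	episodic
HIF2A	1163		2.5	episodic
HIF2A	1165		2.5	episodic
HIF2A	1166		2.5	episodic
HIF2A	1167		2.5	episodic
HIF2A	1234		2.5	episodic
HIF3A	11		2.5	episodic
HIF3A	25		2.5	episodic
HIF3A	89		2.5	episodic
HIF3A	176		2.5	episodic
HIF3A	311		1.0	episodic
HIF3A	456		2.5	episodic
HIF3A	461		2.5	episodic
HIF3A	462		2.5	episodic
HIF3A	483		2.5	episodic
HIF3A	485		2.5	episodic
HIF3A	491		2.5	episodic
HIF3A	516		2.5	episodic
HIF3A	525		2.5	episodic
HIF3A	577		2.5	episodic
HIF3A	597		2.5	episodic
HIF3A	599		2.5	episodic
HIF3A	602		2.5	episodic
HIF3A	610		2.5	episodic
HIF3A	643		2.5	episodic
HIF3A	658		2.5	episodic
HIF3A	670		2.5	episodic
HIF3A	675		2.5	episodic
HIF3A	688		2.5	episodic
HIF3A	720		2.5	episodic
HIF3A	832		2.5	episodic
HIF4A	71		2.5	episodic
HIF4A	160		2.5	episodic
HIF4A	303		2.5	episodic
HIF4A	310		2.5	episodic
HIF4A	394		1.0	episodic
HIF4A	546		2.5	episodic
HIF4A	561		2.5	episodic
HIF4A	715		1.0	episodic
HIF4A	779		2.5	episodic
HIF4A	807		1.0	episodic
HIF4A	854		1.0	episodic
HIF4A	867		1.0	episodic
HIF4A	879		2.5	episodic
HIF4A	892		2.5	episodic
EGLN1	13		2.5	episodic
EGLN1	78		2.5	episodic
EGLN1	79		2.5	episodic
EGLN1	89		2.5	episodic
EGLN1	90		2.5	episodic
EGLN1	91		2.5	episodic
EGLN1	167		2.5	episodic
EGLN1	395		2.5	episodic
EGLN2	21		1.0	episodic
EGLN2	45		1.0	episodic
EGLN2	107		1.0	episodic
EGLN2	245		1.0	episodic
EGLN2	289		1.0	episodic
EGLN2	314		1.0	episodic
EGLN2	316		1.0	episodic
EGLN2	335		2.5	episodic
EGLN2	379		1.0	episodic
EGLN2	442		1.0	episodic
EGLN2	489		2.5	episodic
EGLN2	281		2.5	episodic
EGLN2	593		1.0	episodic
EGLN2	684		2.5	episodic
EGLN2	687		2.5	episodic
EGLN2	693		2.5	episodic
EGLN2	695		2.5	episodic
EGLN2	696		2.5	episodic
EGLN2	697		2.5	episodic
EGLN2	701		2.5	episodic
EGLN3	29		1.0	episodic
EGLN3	211		1.0	episodic
EGLN3	223		1.0	episodic
EGLN3	336		1.0	episodic
EGLN3	376		1.0	episodic
EGLN3	420		1.0	episodic
EGLN3	461		2.5	episodic
EGLN3	469		2.5	episodic
EGLN3	476		2.5	episodic
EGLN3	477		2.5	episodic
HIF1A	543		1.0	pervasive
HIF2A	156		1.0	pervasive
HIF2A	240		1.0	pervasive
HIF2A	268		1.0	pervasive
HIF2A	681		2.5	pervasive
HIF2A	888		1.0	pervasive
HIF2A	1118		1.0	pervasive
HIF3A	11		2.5	pervasive
HIF3A	473		1.0	pervasive
HIF3A	483		2.5	pervasive
HIF3A	516		2.5	pervasive
HIF3A	599		2.5	pervasive
HIF4A	75		1.0	pervasive
HIF4A	394		1.0	pervasive
HIF4A	715		1.0	pervasive
HIF4A	779		2.5	pervasive
HIF4A	892		2.5	pervasive
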