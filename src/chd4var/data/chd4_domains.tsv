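# CHD4 (UniProt Q14839, 1912 aa) domain architecture as named residue intervals,
# 1-based inclusive. kind: domain (top-level, mutually non-overlapping),
# subdomain (nested within `parent`), composite (union/span of other intervals,
# excluded from overlap checks and from interdomain assignment).
# The HMG box interval is approximate: only its length (82 aa) and its containing
# region are established; the interval below is an editorial placement within the
# N-terminal region that contains residue 202 as described for the M202I variant.
name	parent	kind	start	end	note
N_terminal		domain	1	354	IDR1, HMG box, IDR2 and an aggregation-prone region; required for full remodeling activity
HMG	N_terminal	subdomain	161	242	82-aa helical DNA-backbone-binding box; approximate placement
PHD1		domain	363	410	zinc-finger reader of histone H3 tails
PHD2		domain	442	482	zinc-finger reader of histone H3 tails
CD1		domain	522	579	chromodomain; nucleosome binding and ATPase modulation
CD2		domain	615	676	chromodomain; nucleosome binding and ATPase modulation
ATPase		domain	731	915	ATP-binding/hydrolysis lobe of the SNF2-family motor
helicase		domain	1047	1192	energy-transduction lobe of the SNF2-family motor
C_terminal		domain	1230	1912	CTD1/CTD2 with SANT-SLIDE DNA-binding module and autoinhibitory motif
C1a	C_terminal	subdomain	1230	1380	CTD1 ordered region; autoinhibitory
disordered_1	C_terminal	subdomain	1310	1400	predicted disordered segment
C1b	C_terminal	subdomain	1400	1540	CTD1 ordered region (SANT-SLIDE part)
disordered_2	C_terminal	subdomain	1540	1699	predicted disordered linker splitting SANT-SLIDE
C2a	C_terminal	subdomain	1700	1800	CTD2 ordered region; NuRD/ChAHP interaction
C2b	C_terminal	subdomain	1800	1912	CTD2 ordered region
APR2	C2a	subdomain	1735	1742	aggregation-prone region (YWLLAGII); transcription-factor interactions
ATPase_motor_region		composite	731	1192	ATPase + inter-lobe linker + helicase; grouping used for enrichment
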